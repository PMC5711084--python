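"""Bulk electron-density assignment and CT density conversion.

Implements the segmentation and density-override machinery of MRI-only
planning with bulk densities:

* threshold segmentation of bone (HU > 250) and air (HU < -300) on CT,
  with strict inequalities;
* a piecewise-linear HU -> relative-electron-density (RED) calibration for
  the heterogeneity-corrected CT arm;
* the three bulk schemes applied to MRI — W (all water), W+B (bone and
  teeth at RED 1.45), W+B+A (additionally air at RED 0) — plus the CT-arm
  implant/artifact overrides (implant RED 3.0 via mask, artifact shell
  water-equivalent);
* the contour-cropping rules (metric 5 mm inner margin, inferior cut with
  internal contours retained 1 cm higher) and the implant-slab sPTV
  extraction.

The engine works exclusively in RED (water = 1.0): megavoltage photon
attenuation scales with electron density, and the bulk bone value is the
published pair 1.53 g/cm^3 <-> RED 1.45, of which RED is the operative
number (both are kept as a labelled constant pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import StructureSet, TissueClass, Volume

__all__ = [
    "BONE_BULK_DENSITY_G_CM3",
    "BONE_BULK_RED",
    "CalibrationCurve",
    "BulkScheme",
    "segment_by_threshold",
    "hu_to_red",
    "build_density_scheme",
    "build_ct_density",
    "crop_structures",
    "extract_sptv",
]

# Published bulk-bone pair: physical density and the operative RED value.
BONE_BULK_DENSITY_G_CM3 = 1.53
BONE_BULK_RED = 1.45
IMPLANT_RED_DEFAULT = 3.0


@dataclass
class CalibrationCurve:
    """Piecewise-linear HU -> RED calibration, clamped at its endpoints.

    The default control points anchor air (-1000, 0), water (0, 1), the
    published bulk-bone pair at the phantom's bone HU (700, 1.45), tooth
    enamel (1400, 1.84, linear continuation at the same slope), and the
    scanner ceiling (3071, 3.0).  Anchoring bone at 700 makes the CT arm
    and the bulk schemes agree exactly on phantom bone, isolating scheme
    effects from calibration effects.
    """

    hu: np.ndarray = field(
        default_factory=lambda: np.array([-1000.0, 0.0, 700.0, 1400.0, 3071.0])
    )
    red: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 1.45, 1.84, 3.0])
    )

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.hu.ndim != 1 or self.hu.shape != self.red.shape:
            raise ValueError("hu and red must be 1D arrays of equal length")
        if not np.all(np.diff(self.hu) > 0):
            raise ValueError("HU control points must be strictly increasing")
        if not np.all(np.diff(self.red) >= 0):
            raise ValueError("RED control points must be non-decreasing")
        if self.hu[0] > -1000.0 or self.hu[-1] < 3071.0:
            raise ValueError("curve must cover [-1000, 3071] HU")

    def __call__(self, hu_values: np.ndarray) -> np.ndarray:
        return np.interp(hu_values, self.hu, self.red)


@dataclass
class BulkScheme:
    """A bulk density-assignment scheme for the MRI arm.

    ``W`` maps every in-body voxel to water; ``W+B`` additionally maps
    bone and teeth (and, reproducing the known failure mode, implants —
    invisible on MRI and assigned tooth/bone density) to
    ``bone_red``; ``W+B+A`` also maps air cavities to ``air_red``.
    """

    scheme_id: str  # "W" | "W+B" | "W+B+A"
    soft_red: float = 1.0
    bone_red: float = BONE_BULK_RED
    air_red: float = 0.0
    red_max: float = IMPLANT_RED_DEFAULT

    VALID = ("W", "W+B", "W+B+A")

    def __post_init__(self) -> None:
        if self.scheme_id not in self.VALID:
            raise ValueError(f"unknown scheme {self.scheme_id!r}; expected one of {self.VALID}")


def segment_by_threshold(
    ct: Volume,
    bone_hu: float = 250.0,
    air_hu: float = -300.0,
    body: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold-segment bone and air inside the body contour.

    Strict inequalities exactly as specified: bone is HU > ``bone_hu``,
    air is HU < ``air_hu``; a voxel at either threshold value belongs to
    neither mask.  Returns ``(bone, air)`` boolean masks (disjoint).
    """
    if bone_hu <= air_hu:
        raise ValueError(f"bone threshold {bone_hu} must exceed air threshold {air_hu}")
    vals = ct.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("CT values must be finite")
    if body is None:
        body = np.ones(vals.shape, dtype=bool)
    elif body.shape != vals.shape:
        raise ValueError("body mask must share the CT grid")
    bone = (vals > bone_hu) & body
    air = (vals < air_hu) & body
    return bone, air


def hu_to_red(ct: Volume, curve: CalibrationCurve | None = None) -> Volume:
    """Voxelwise piecewise-linear HU -> RED conversion (clamped)."""
    curve = curve or CalibrationCurve()
    return ct.like(curve(ct.values).astype(np.float32))


def build_density_scheme(
    labels_or_masks,
    body: np.ndarray,
    scheme: BulkScheme | str,
    implant_mask: np.ndarray | None = None,
    artifact_mask: np.ndarray | None = None,
    *,
    spacing_mm=None,
    origin_mm=None,
) -> Volume:
    """Build the relative-electron-density volume for one MRI bulk scheme.

    Parameters
    ----------
    labels_or_masks
        Either a :class:`~mribulk.volume.LabelMap` or a dict of boolean
        masks with keys ``bone``, ``air``, and optionally ``teeth``.
    body
        Body contour mask; everything outside is RED 0.
    scheme
        A :class:`BulkScheme` or its id string.
    implant_mask
        Implant voxels.  On the MRI arm these are *treated as teeth*
        (bulk bone-equivalent RED), reproducing the known failure mode of
        implants that are invisible on MRI.
    artifact_mask
        Streak-artifact shell voxels; on the MRI arm they are soft tissue
        (water).  (The CT arm's overrides live in :func:`build_ct_density`.)
    """
    if isinstance(scheme, str):
        scheme = BulkScheme(scheme)
    from .volume import LabelMap  # local import to avoid cycle in typing

    if isinstance(labels_or_masks, LabelMap):
        lm = labels_or_masks
        bone = lm.mask(TissueClass.BONE)
        air = lm.mask(TissueClass.AIR)
        teeth = lm.mask(TissueClass.TOOTH)
        if implant_mask is None:
            implant_mask = lm.mask(TissueClass.IMPLANT)
        if spacing_mm is None:
            spacing_mm = lm.volume.spacing_mm
            origin_mm = lm.volume.origin_mm
    else:
        bone = np.asarray(labels_or_masks["bone"], dtype=bool)
        air = np.asarray(labels_or_masks["air"], dtype=bool)
        teeth = np.asarray(labels_or_masks.get("teeth", np.zeros_like(bone)), dtype=bool)
    if spacing_mm is None:
        raise ValueError("spacing_mm/origin_mm required when passing raw masks")
    for m, name in ((bone, "bone"), (air, "air"), (teeth, "teeth")):
        if m.shape != body.shape:
            raise ValueError(f"{name} mask does not share the reference grid")
    if implant_mask is not None and (implant_mask & air).any():
        raise ValueError("implant and air masks overlap")

    red = np.zeros(body.shape, dtype=np.float32)
    red[body] = scheme.soft_red
    if scheme.scheme_id in ("W+B", "W+B+A"):
        dense = (bone | teeth) & body
        if implant_mask is not None:
            dense |= implant_mask & body  # implants pass as teeth on MRI
        red[dense] = scheme.bone_red
        if scheme.scheme_id == "W+B+A":
            red[air & body] = scheme.air_red
    return Volume(red, np.asarray(spacing_mm, float), np.asarray(origin_mm, float))


def build_ct_density(
    ct: Volume,
    body: np.ndarray,
    curve: CalibrationCurve | None = None,
    implant_mask: np.ndarray | None = None,
    artifact_mask: np.ndarray | None = None,
    implant_red: float = IMPLANT_RED_DEFAULT,
) -> Volume:
    """Heterogeneity-corrected CT density arm.

    HU -> RED through the calibration curve, with the clinical metal
    workflow applied through masks: streak-artifact voxels are forced
    water-equivalent (their Hounsfield numbers are unreliable) and implant
    voxels are overridden to ``implant_red`` (default 3.0).  Outside the
    body contour the density is 0.
    """
    if implant_mask is not None and artifact_mask is not None:
        if (implant_mask & artifact_mask).any():
            raise ValueError("implant and artifact masks overlap")
    red = hu_to_red(ct, curve).values.copy()
    red[~body] = 0.0
    if artifact_mask is not None:
        red[artifact_mask & body] = 1.0
    if implant_mask is not None:
        red[implant_mask & body] = implant_red
    return ct.like(red)


def crop_structures(
    structs: StructureSet,
    body: np.ndarray | None = None,
    inner_margin_mm: float = 5.0,
    inferior_cut_mm: float | None = None,
    internal_extra_mm: float = 10.0,
) -> StructureSet:
    """Apply the contour-standardization cropping rules.

    Internal contours are intersected with the body eroded by
    ``inner_margin_mm`` (metric erosion via Euclidean distance transform —
    voxel anisotropy makes structuring-element erosion wrong) and, when an
    inferior cut plane is given, retained only ``internal_extra_mm`` above
    it; the BODY contour itself is cut at the plane.  Idempotent for the
    default parameters (margin <= internal_extra).
    """
    if inner_margin_mm < 0:
        raise ValueError("margin must be >= 0")
    out = structs.copy()
    if body is None:
        body = structs["BODY"]
    body = np.asarray(body, dtype=bool)

    zs = structs.origin_mm[2] + structs.spacing_mm[2] * np.arange(body.shape[2])
    if inferior_cut_mm is not None:
        if not (zs[0] <= inferior_cut_mm <= zs[-1]):
            raise ValueError(
                f"inferior cut {inferior_cut_mm} mm outside volume z-range "
                f"[{zs[0]}, {zs[-1]}]"
            )
        body = body & (zs >= inferior_cut_mm)[None, None, :]
        if not body.any():
            raise ValueError("inferior cut empties the BODY contour")

    if inner_margin_mm > 0:
        depth = ndimage.distance_transform_edt(body, sampling=structs.spacing_mm)
        eroded = depth >= inner_margin_mm
        if not eroded.any():
            raise ValueError("erosion empties the BODY contour")
    else:
        eroded = body

    keep_internal = eroded
    if inferior_cut_mm is not None:
        keep_internal = keep_internal & (zs >= inferior_cut_mm + internal_extra_mm)[
            None, None, :
        ]

    for name in out.names:
        if name == "BODY":
            out.masks[name] = body
        else:
            out.masks[name] = out.masks[name] & keep_internal
    return out


def extract_sptv(struct: np.ndarray, implant_mask: np.ndarray) -> np.ndarray:
    """Restrict a target mask to the axial-slice range containing implants.

    The sub-PTV is the target intersected with the contiguous z-slice
    interval [min, max] over slices holding any implant voxel.
    """
    struct = np.asarray(struct, dtype=bool)
    implant_mask = np.asarray(implant_mask, dtype=bool)
    if struct.shape != implant_mask.shape:
        raise ValueError("masks must share the grid")
    if not implant_mask.any():
        raise ValueError("implant mask is empty")
    z_any = np.nonzero(implant_mask.any(axis=(0, 1)))[0]
    z0, z1 = int(z_any.min()), int(z_any.max())
    out = np.zeros_like(struct)
    out[:, :, z0 : z1 + 1] = struct[:, :, z0 : z1 + 1]
    return out
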