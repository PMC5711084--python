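"""Synthetic digital phantoms.

Two families of inputs are generated here:

* Paired pseudo-CT / pseudo-MRI head-and-neck phantoms with a ground-truth
  tissue label map and a planning structure set.  Anatomy is procedural
  (elliptical head with a cranial dome, cylindrical neck, sinonasal air
  boxes, mandible and tooth arcs, optional dental implants with
  streak-artifact shells): only the topological features that drive
  heterogeneity effects — bone shells, air pockets, teeth and implants near
  the targets — are modelled, with every dimension exposed in the config.
* An ACR-style cylindrical grid phantom (20 cm diameter, 17 cm length,
  1.5 cm square grid) with analytically known intersection coordinates and
  optional parametric geometric distortion, for the distortion-QA pipeline.

Default CT numbers sit comfortably inside the segmentation threshold
regions (bone 700 HU > 250, air -1000 HU < -300) so that threshold
segmentation recovers the generating labels exactly; the streak-artifact
shell draws HU uniformly in [-500, 500], deterministically from the seed,
emulating the corrupted Hounsfield numbers around dental hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelMap, StructureSet, TissueClass, Volume, centered_grid

__all__ = [
    "DistortionField",
    "GridPhantomTruth",
    "GridPhantomConfig",
    "HeadPhantomConfig",
    "NeckPhantomConfig",
    "make_distortion_field",
    "apply_distortion",
    "make_grid_phantom",
    "make_head_phantom",
    "make_neck_phantom",
]


# ---------------------------------------------------------------------------
# Distortion fields
# ---------------------------------------------------------------------------


@dataclass
class DistortionField:
    """Parametric displacement field ``position_mm -> displacement_mm``.

    Families
    --------
    ``uniform``
        Constant shift; params: ``shift_mm`` (3-vector).
    ``radial_poly``
        In-plane radial displacement whose magnitude is a polynomial in the
        distance r from the scanner axis: ``|d|(r) = sum_k c_k r^k``,
        directed radially outward; params: ``coeffs`` (ascending powers),
        optional ``center_mm`` (axis offset in the axial plane, emulating a
        phantom scanned off-isocenter).
    ``axis_poly``
        Independent per-axis polynomials in the matching coordinate;
        params: ``coeffs_x/y/z``.
    """

    family: str
    params: dict
    max_displacement_mm: float | None = None

    def displacement(self, points_mm: np.ndarray) -> np.ndarray:
        """Evaluate displacement (mm) at arbitrary world points (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        if pts.shape[-1] != 3:
            raise ValueError("points must have 3 components")
        if self.family == "uniform":
            shift = np.asarray(self.params["shift_mm"], dtype=float).reshape(3)
            return np.broadcast_to(shift, pts.shape).copy()
        if self.family == "radial_poly":
            center = np.asarray(self.params.get("center_mm", (0.0, 0.0)), float)
            coeffs = np.asarray(self.params["coeffs"], dtype=float)
            dxy = pts[:, :2] - center
            r = np.hypot(dxy[:, 0], dxy[:, 1])
            mag = np.polynomial.polynomial.polyval(r, coeffs)
            unit = np.where(r[:, None] > 0, dxy / np.maximum(r, 1e-300)[:, None], 0.0)
            out = np.zeros_like(pts)
            out[:, :2] = unit * mag[:, None]
            return out
        if self.family == "axis_poly":
            out = np.zeros_like(pts)
            for ax, key in enumerate(("coeffs_x", "coeffs_y", "coeffs_z")):
                coeffs = np.asarray(self.params.get(key, [0.0]), dtype=float)
                out[:, ax] = np.polynomial.polynomial.polyval(pts[:, ax], coeffs)
            return out
        raise ValueError(f"unknown distortion family: {self.family!r}")

    def __call__(self, points_mm: np.ndarray) -> np.ndarray:
        return self.displacement(points_mm)


def make_distortion_field(family: str, params: dict | None = None) -> DistortionField:
    """Construct a distortion field.

    Besides raw coefficients, the ``radial_poly`` family accepts a
    calibration form ``{"degree": k, "amplitude_mm": A, "r_ref_mm": R}``
    producing ``|d|(r) = A * (r / R)^k``.  A cubic calibrated to 4 mm at
    r = 170 mm (the body-contour distortion observed 17 cm lateral to
    isocenter) stays below 1 mm for r <= 100 mm, matching the
    sub-millimetre distortion within a 20 cm region around isocenter.
    """
    params = dict(params or {})
    if family == "uniform":
        params.setdefault("shift_mm", (0.0, 0.0, 0.0))
        shift = np.asarray(params["shift_mm"], float)
        return DistortionField("uniform", params, float(np.linalg.norm(shift)))
    if family == "radial_poly":
        if "coeffs" not in params:
            degree = int(params.pop("degree", 3))
            amp = float(params.pop("amplitude_mm", 4.0))
            r_ref = float(params.pop("r_ref_mm", 170.0))
            coeffs = np.zeros(degree + 1)
            coeffs[degree] = amp / r_ref**degree
            params["coeffs"] = coeffs
            params.setdefault("r_ref_mm_calibration", r_ref)
        return DistortionField("radial_poly", params)
    if family == "axis_poly":
        return DistortionField("axis_poly", params)
    raise ValueError(f"unknown distortion family: {family!r}")


def apply_distortion(vol: Volume, fld: DistortionField) -> Volume:
    """Warp a volume by a distortion field (pull-back resampling).

    ``output(p) = input(p - displacement(p))`` with linear interpolation;
    out-of-volume samples fill with 0.  A feature at ``p0`` thereby
    appears at the point ``p`` solving ``p - displacement(p) = p0``, which
    is how truth coordinates are warped analytically in
    :func:`make_grid_phantom`; for a uniform shift this is exactly
    ``p0 + shift``.
    """
    ax = [vol.axis_coordinates(i) for i in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    sample = pts - fld.displacement(pts)
    idx = vol.world_to_index(sample).T  # (3, N)
    out = ndimage.map_coordinates(
        vol.values.astype(np.float32, copy=False), idx, order=1,
        mode="constant", cval=0.0,
    ).reshape(vol.shape)
    return vol.like(out)


# ---------------------------------------------------------------------------
# ACR-style grid phantom
# ---------------------------------------------------------------------------


@dataclass
class GridPhantomConfig:
    """Layout of the cylindrical grid phantom and its imaging grid.

    Defaults mirror a 25 cm field of view on a 256 x 256 matrix with the
    standard insert: 20 cm diameter, 17 cm length, 1.5 cm square grid.
    ``clip_radius_mm`` limits which intersections count as landmarks; any
    value in [15*sqrt(34) ~ 87.46, 90) mm yields the canonical 109 interior
    points, and the grid lines extend to ``line_radius_mm`` (< 90 mm) so
    that exactly those 109 intersections are rendered in the image.
    """

    matrix: int = 256
    fov_mm: float = 250.0
    slice_thickness_mm: float = 5.0
    n_slices: int = 1
    diameter_mm: float = 200.0
    length_mm: float = 170.0
    grid_spacing_mm: float = 15.0
    clip_radius_mm: float = 88.0
    line_radius_mm: float = 89.0
    line_width_mm: float = 1.6
    line_amplitude: float = 100.0
    background_level: float = 120.0
    noise_sd: float = 0.0

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix


@dataclass
class GridPhantomTruth:
    """Grid-phantom image pair with analytically known intersections."""

    grid_image: Volume
    background_image: Volume
    intersections_mm: np.ndarray  # (N, 2) axial-plane coordinates, mm
    grid_spacing_mm: float
    diameter_mm: float
    length_mm: float


def _grid_intersections(cfg: GridPhantomConfig) -> np.ndarray:
    p = cfg.grid_spacing_mm
    n = int(np.floor(cfg.diameter_mm / 2 / p))
    coords = p * np.arange(-n, n + 1)
    gx, gy = np.meshgrid(coords, coords, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    keep = np.hypot(pts[:, 0], pts[:, 1]) <= cfg.clip_radius_mm
    return pts[keep]


def make_grid_phantom(
    config: GridPhantomConfig | None = None,
    distortion: DistortionField | None = None,
    seed: int = 0,
) -> GridPhantomTruth:
    """Generate the grid phantom image, its background image, and truth.

    The grid image is the background image plus an additive bright-line
    pattern (one top-hat profile per line direction, so intersections carry
    twice the single-line amplitude and survive smoothing as local maxima).
    When a distortion field is given, both images are warped by pull-back
    resampling and the truth coordinates are warped analytically by the
    same field (``p -> p + d(p)``).
    """
    cfg = config or GridPhantomConfig()
    if cfg.grid_spacing_mm <= 2 * cfg.pixel_mm:
        raise ValueError(
            f"grid spacing {cfg.grid_spacing_mm} mm <= 2x pixel size "
            f"{cfg.pixel_mm:.3f} mm: lines unresolvable"
        )
    shape = (cfg.matrix, cfg.matrix, cfg.n_slices)
    base = centered_grid(shape, (cfg.pixel_mm, cfg.pixel_mm, cfg.slice_thickness_mm))
    xs, ys, _ = base.coordinate_grids()
    r2d = np.hypot(xs, ys)  # (nx, ny, 1)
    inside = np.broadcast_to(r2d <= cfg.diameter_mm / 2, shape)

    rng = np.random.default_rng(seed)
    background = np.where(inside, np.float32(cfg.background_level), np.float32(0.0))
    if cfg.noise_sd > 0:
        background = background + rng.normal(0.0, cfg.noise_sd, size=shape).astype(
            np.float32
        )

    p = cfg.grid_spacing_mm
    n = int(np.floor(cfg.diameter_mm / 2 / p))
    line_coords = p * np.arange(-n, n + 1)
    half_w = cfg.line_width_mm / 2
    px = cfg.pixel_mm
    in_extent = (r2d <= cfg.line_radius_mm).astype(np.float32)
    lines = np.zeros((cfg.matrix, cfg.matrix, 1), dtype=np.float32)

    def _coverage(coord: np.ndarray, c: float) -> np.ndarray:
        # fractional overlap of the pixel footprint with the line band
        # (anti-aliased rendering keeps the line center faithful)
        overlap = np.minimum(coord + px / 2, c + half_w) - np.maximum(
            coord - px / 2, c - half_w
        )
        return np.clip(overlap / px, 0.0, 1.0).astype(np.float32)

    for c in line_coords:
        if abs(c) > cfg.line_radius_mm:
            continue
        lines += cfg.line_amplitude * (_coverage(xs, c) + _coverage(ys, c)) * in_extent
    grid_vals = background + np.broadcast_to(lines, shape)

    bg_vol = base.like(np.ascontiguousarray(background, dtype=np.float32))
    grid_vol = base.like(np.ascontiguousarray(grid_vals, dtype=np.float32))

    pts2 = _grid_intersections(cfg)
    if distortion is not None:
        grid_vol = apply_distortion(grid_vol, distortion)
        bg_vol = apply_distortion(bg_vol, distortion)
        pts3 = np.concatenate([pts2, np.zeros((len(pts2), 1))], axis=1)
        # Analytic truth warp, exactly consistent with pull-back image
        # resampling: the warped point p solves p - d(p) = p0 (fixed-point
        # iteration; converges for the smooth sub-unit-gradient fields
        # used here, and is exact in one step for uniform shifts).
        warped = pts3 + distortion.displacement(pts3)
        for _ in range(40):
            warped = pts3 + distortion.displacement(warped)
        pts2 = warped[:, :2]

    return GridPhantomTruth(
        grid_image=grid_vol,
        background_image=bg_vol,
        intersections_mm=pts2,
        grid_spacing_mm=cfg.grid_spacing_mm,
        diameter_mm=cfg.diameter_mm,
        length_mm=cfg.length_mm,
    )


# ---------------------------------------------------------------------------
# Head-and-neck phantom
# ---------------------------------------------------------------------------


@dataclass
class HeadPhantomConfig:
    """Procedural head-and-neck anatomy; all dimensions in mm.

    The default grid is 2 mm isotropic (the planning dose-grid pitch); a
    CT-like 1 x 1 x 2 mm grid can be requested via ``spacing_mm``.  The
    world origin (= machine isocenter) sits at the nominal PTV70 center.

    Body model: an elliptical face/cranium column capped by a dome, on a
    cylindrical neck.  The cranial vault is a bone shell obtained by
    differencing metric erosions of the body (skin 6 mm, shell 8 mm thick)
    above ``skull_base_z``; mandible and tooth arcs curve around the mouth
    center; dental implants (optional) are embedded in the tooth arc where
    the anterior fields project onto the target's inferior slices.
    """

    shape: tuple[int, int, int] = (110, 110, 84)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    # body (world mm)
    face_center_xy: tuple[float, float] = (0.0, 5.0)
    face_semiaxes_xy: tuple[float, float] = (70.0, 85.0)
    face_z: tuple[float, float] = (-48.0, 40.0)
    dome_height: float = 40.0
    neck_center_xy: tuple[float, float] = (0.0, -5.0)
    neck_radius: float = 46.0

    # skull shell
    skin_mm: float = 6.0
    skull_thickness_mm: float = 8.0
    skull_base_z: float = -25.0

    # air cavities (sinonasal boxes anterior of the target)
    sinus_centers: tuple = ((-20.0, 45.0, 8.0), (20.0, 45.0, 8.0), (0.0, 55.0, 0.0))
    sinus_half_sizes: tuple = ((10.0, 11.0, 10.0), (10.0, 11.0, 10.0), (8.0, 12.0, 12.0))

    # mandible / teeth arcs around the mouth center
    mouth_center_xy: tuple[float, float] = (0.0, 42.0)
    mandible_r: tuple[float, float] = (38.0, 47.0)
    mandible_z: tuple[float, float] = (-44.0, -22.0)
    teeth_r: tuple[float, float] = (29.0, 37.0)
    teeth_z: tuple[float, float] = (-36.0, -14.0)
    arc_half_angle_deg: float = 78.0

    with_implants: bool = False
    implant_centers_xy: tuple = ((-10.0, 73.0), (10.0, 73.0))
    implant_half_size: tuple[float, float] = (4.5, 4.5)
    implant_z: tuple[float, float] = (-30.0, -18.0)
    artifact_margin_mm: float = 6.0

    # targets and organs at risk
    ptv70_center: tuple[float, float, float] = (0.0, 10.0, -4.0)
    ptv70_radius: float = 24.0
    ptv63_margin: float = 10.0
    ptv59_margin: float = 6.0
    brainstem_xy: tuple[float, float] = (0.0, -42.0)
    brainstem_radius: float = 7.0
    brainstem_z: tuple[float, float] = (-10.0, 55.0)
    cord_xy: tuple[float, float] = (0.0, -42.0)
    cord_radius: float = 5.0
    cord_z_top: float = -10.0
    chiasm_center: tuple[float, float, float] = (0.0, -5.0, 42.0)
    chiasm_half: tuple[float, float, float] = (7.0, 5.0, 4.0)
    optic_nerve_x: float = 14.0
    optic_nerve_y: tuple[float, float] = (5.0, 25.0)
    optic_nerve_z: float = 42.0
    optic_nerve_radius: float = 2.5

    # CT numbers (HU) per tissue class
    hu_soft: float = 40.0
    hu_bone: float = 700.0
    hu_air: float = -1000.0
    hu_tooth: float = 1400.0
    hu_implant: float = 3000.0
    hu_outside: float = -1000.0
    artifact_hu_range: tuple[float, float] = (-500.0, 500.0)

    # MRI intensities; teeth/implants share the air (signal-void) intensity
    # and the artifact shell shares soft tissue, so none of them is
    # distinguishable on the MRI alone.
    mri_soft: float = 400.0
    mri_bone: float = 120.0
    mri_air: float = 25.0
    mri_noise_sd: float = 8.0

    jitter_mm: float = 2.0


def _box(xs, ys, zs, center, half) -> np.ndarray:
    cx, cy, cz = center
    hx, hy, hz = half
    return (np.abs(xs - cx) <= hx) & (np.abs(ys - cy) <= hy) & (np.abs(zs - cz) <= hz)


def make_head_phantom(
    config: HeadPhantomConfig | None = None, seed: int = 0
) -> tuple[LabelMap, Volume, Volume, StructureSet]:
    """Generate a paired pseudo-CT / pseudo-MRI head phantom.

    Returns ``(labels, ct, mri, structures)`` on one shared grid; fully
    deterministic for a fixed ``(config, seed)``.  The seed drives small
    per-patient anatomical jitter (face size, target position and radius),
    the streak-artifact HU pattern, and MRI noise.
    """
    cfg = config or HeadPhantomConfig()
    if any(s <= 0 for s in cfg.spacing_mm) or any(n <= 0 for n in cfg.shape):
        raise ValueError("shape and spacing must be strictly positive")
    rng = np.random.default_rng(seed)

    j = cfg.jitter_mm
    face_ax = np.asarray(cfg.face_semiaxes_xy) + rng.uniform(-j, j, 2)
    ptv_center = np.asarray(cfg.ptv70_center) + rng.uniform(-j / 2, j / 2, 3)
    ptv_radius = cfg.ptv70_radius + rng.uniform(-j / 2, j / 2)

    base = centered_grid(cfg.shape, cfg.spacing_mm)
    xs, ys, zs = base.coordinate_grids()
    xs, ys, zs = np.broadcast_arrays(xs, ys, zs)

    fx, fy = cfg.face_center_xy
    ell2 = ((xs - fx) / face_ax[0]) ** 2 + ((ys - fy) / face_ax[1]) ** 2
    z_lo, z_hi = cfg.face_z
    face = (ell2 <= 1.0) & (zs >= z_lo) & (zs <= z_hi)
    dome = (ell2 + ((zs - z_hi) / cfg.dome_height) ** 2 <= 1.0) & (zs > z_hi)
    neck = (
        np.hypot(xs - cfg.neck_center_xy[0], ys - cfg.neck_center_xy[1]) <= cfg.neck_radius
    ) & (zs < z_lo)
    body = face | dome | neck

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[body] = int(TissueClass.SOFT)

    # Cranial vault: metric shell between skin and skin + thickness depths,
    # restricted above the skull base so beams at target level cross it.
    edt_body = ndimage.distance_transform_edt(body, sampling=cfg.spacing_mm)
    skull = (
        (edt_body > cfg.skin_mm)
        & (edt_body <= cfg.skin_mm + cfg.skull_thickness_mm)
        & (zs >= cfg.skull_base_z)
    )
    labels[skull] = int(TissueClass.BONE)

    # Mandible and tooth arcs.
    mx, my = cfg.mouth_center_xy
    r_mouth = np.hypot(xs - mx, ys - my)
    ang = np.degrees(np.arctan2(xs - mx, ys - my))  # 0 deg = anterior (+y)
    in_arc = np.abs(ang) <= cfg.arc_half_angle_deg
    mandible = (
        in_arc
        & (r_mouth >= cfg.mandible_r[0]) & (r_mouth <= cfg.mandible_r[1])
        & (zs >= cfg.mandible_z[0]) & (zs <= cfg.mandible_z[1])
        & body
    )
    labels[mandible] = int(TissueClass.BONE)
    teeth = (
        in_arc
        & (r_mouth >= cfg.teeth_r[0]) & (r_mouth <= cfg.teeth_r[1])
        & (zs >= cfg.teeth_z[0]) & (zs <= cfg.teeth_z[1])
        & body
    )
    labels[teeth] = int(TissueClass.TOOTH)

    # Sinonasal air cavities (after bone so they carve cleanly).
    for c, h in zip(cfg.sinus_centers, cfg.sinus_half_sizes):
        labels[_box(xs, ys, zs, c, h) & body] = int(TissueClass.AIR)
    air = labels == int(TissueClass.AIR)
    teeth = labels == int(TissueClass.TOOTH)

    if cfg.with_implants:
        if not teeth.any():
            raise ValueError("implants requested but the config has no tooth region")
        implant = np.zeros_like(teeth)
        zc = (cfg.implant_z[0] + cfg.implant_z[1]) / 2
        hz = (cfg.implant_z[1] - cfg.implant_z[0]) / 2
        for cx, cy in cfg.implant_centers_xy:
            implant |= _box(xs, ys, zs, (cx, cy, zc), (*cfg.implant_half_size, hz))
        implant &= teeth  # implants replace tooth material
        if not implant.any():
            raise ValueError("implant boxes do not intersect the tooth arc")
        # Streak-artifact shell: soft tissue ring around the implants.
        edt_imp = ndimage.distance_transform_edt(~implant, sampling=cfg.spacing_mm)
        shell = (edt_imp <= cfg.artifact_margin_mm) & ~implant
        shell &= labels == int(TissueClass.SOFT)
        labels[implant] = int(TissueClass.IMPLANT)
        labels[shell] = int(TissueClass.ARTIFACT)

    # --- CT (HU) ------------------------------------------------------
    hu_by_class = {
        TissueClass.OUTSIDE: cfg.hu_outside,
        TissueClass.SOFT: cfg.hu_soft,
        TissueClass.BONE: cfg.hu_bone,
        TissueClass.AIR: cfg.hu_air,
        TissueClass.TOOTH: cfg.hu_tooth,
        TissueClass.IMPLANT: cfg.hu_implant,
    }
    ct = np.full(cfg.shape, cfg.hu_outside, dtype=np.float32)
    for cls, hu in hu_by_class.items():
        ct[labels == int(cls)] = hu
    artifact = labels == int(TissueClass.ARTIFACT)
    if artifact.any():
        lo, hi = cfg.artifact_hu_range
        ct[artifact] = rng.uniform(lo, hi, size=int(artifact.sum())).astype(np.float32)

    # --- MRI ----------------------------------------------------------
    mri = np.zeros(cfg.shape, dtype=np.float32)
    mri[labels == int(TissueClass.SOFT)] = cfg.mri_soft
    mri[labels == int(TissueClass.BONE)] = cfg.mri_bone
    mri[air] = cfg.mri_air
    mri[labels == int(TissueClass.TOOTH)] = cfg.mri_air
    mri[labels == int(TissueClass.IMPLANT)] = cfg.mri_air
    mri[artifact] = cfg.mri_soft
    if cfg.mri_noise_sd > 0:
        mri += rng.normal(0.0, cfg.mri_noise_sd, size=cfg.shape).astype(np.float32)

    # --- Structures ---------------------------------------------------
    # Targets exclude air cavities (no dose is deposited in air) but may
    # contain bone/teeth.
    dist2 = (
        (xs - ptv_center[0]) ** 2 + (ys - ptv_center[1]) ** 2 + (zs - ptv_center[2]) ** 2
    )
    ptv70 = (dist2 <= ptv_radius**2) & body & ~air
    edt70 = ndimage.distance_transform_edt(~ptv70, sampling=cfg.spacing_mm)
    ptv63 = ((edt70 <= cfg.ptv63_margin) | ptv70) & body & ~air
    edt63 = ndimage.distance_transform_edt(~ptv63, sampling=cfg.spacing_mm)
    ptv59 = ((edt63 <= cfg.ptv59_margin) | ptv63) & body & ~air

    bs = (
        (np.hypot(xs - cfg.brainstem_xy[0], ys - cfg.brainstem_xy[1]) <= cfg.brainstem_radius)
        & (zs >= cfg.brainstem_z[0]) & (zs <= cfg.brainstem_z[1]) & body
    )
    cord = (
        (np.hypot(xs - cfg.cord_xy[0], ys - cfg.cord_xy[1]) <= cfg.cord_radius)
        & (zs <= cfg.cord_z_top) & body
    )
    cord5 = (
        (ndimage.distance_transform_edt(~cord, sampling=cfg.spacing_mm) <= 5.0) | cord
    ) & body
    chiasm = _box(xs, ys, zs, cfg.chiasm_center, cfg.chiasm_half) & body
    on_l = (
        (np.hypot(xs + cfg.optic_nerve_x, zs - cfg.optic_nerve_z) <= cfg.optic_nerve_radius)
        & (ys >= cfg.optic_nerve_y[0]) & (ys <= cfg.optic_nerve_y[1]) & body
    )
    on_r = (
        (np.hypot(xs - cfg.optic_nerve_x, zs - cfg.optic_nerve_z) <= cfg.optic_nerve_radius)
        & (ys >= cfg.optic_nerve_y[0]) & (ys <= cfg.optic_nerve_y[1]) & body
    )

    structs = StructureSet(
        {
            "BODY": body,
            "PTV70": ptv70,
            "PTV63": ptv63,
            "PTV59": ptv59,
            "brainstem": bs,
            "cord": cord,
            "cord+5mm": cord5,
            "chiasm": chiasm,
            "optic_nerve_l": on_l,
            "optic_nerve_r": on_r,
        },
        base.spacing_mm,
        base.origin_mm,
    )

    label_map = LabelMap(Volume(labels, base.spacing_mm, base.origin_mm))
    ct_vol = Volume(ct, base.spacing_mm, base.origin_mm)
    mri_vol = Volume(mri, base.spacing_mm, base.origin_mm)
    return label_map, ct_vol, mri_vol, structs


# ---------------------------------------------------------------------------
# Neck/shoulder phantom for the body-contour-error experiment
# ---------------------------------------------------------------------------


@dataclass
class NeckPhantomConfig:
    """Neck with an elliptical shoulder slab, for contour-error studies.

    The shoulder cross-section is an ellipse reaching ~17 cm laterally
    from the axis over the inferior slices; the PTV63 surrogate extends
    inferiorly into those slices.  The body is water-equivalent so the
    contour-error experiment isolates the pure geometric effect.
    """

    shape: tuple[int, int, int] = (184, 96, 56)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    neck_radius: float = 46.0
    neck_center_xy: tuple[float, float] = (0.0, -5.0)
    shoulder_half_x: float = 170.0
    shoulder_half_y: float = 80.0
    shoulder_z_top: float = -10.0
    ptv63_center: tuple[float, float, float] = (0.0, -10.0, 0.0)
    ptv63_semiaxes: tuple[float, float, float] = (22.0, 22.0, 34.0)
    hu_soft: float = 0.0


def make_neck_phantom(
    config: NeckPhantomConfig | None = None, seed: int = 0
) -> tuple[LabelMap, Volume, StructureSet]:
    """Water-equivalent neck + shoulder phantom with a PTV63 target."""
    cfg = config or NeckPhantomConfig()
    base = centered_grid(cfg.shape, cfg.spacing_mm)
    xs, ys, zs = base.coordinate_grids()
    xs, ys, zs = np.broadcast_arrays(xs, ys, zs)

    neck = np.hypot(xs - cfg.neck_center_xy[0], ys - cfg.neck_center_xy[1]) <= cfg.neck_radius
    shoulder = (
        ((xs / cfg.shoulder_half_x) ** 2 + (ys / cfg.shoulder_half_y) ** 2 <= 1.0)
        & (zs <= cfg.shoulder_z_top)
    )
    body = neck | shoulder

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[body] = int(TissueClass.SOFT)

    cx, cy, cz = cfg.ptv63_center
    ax_, ay, az = cfg.ptv63_semiaxes
    ptv63 = (
        ((xs - cx) / ax_) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0
    ) & body

    ct = np.full(cfg.shape, -1000.0, dtype=np.float32)
    ct[body] = cfg.hu_soft

    structs = StructureSet({"BODY": body, "PTV63": ptv63}, base.spacing_mm, base.origin_mm)
    return (
        LabelMap(Volume(labels, base.spacing_mm, base.origin_mm)),
        Volume(ct, base.spacing_mm, base.origin_mm),
        structs,
    )
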