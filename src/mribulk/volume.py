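"""Core spatial containers: scalar volumes, tissue label maps, structure sets.

Conventions used throughout the package:

* Right-handed patient axes: x lateral (patient left positive), y
  anterior-posterior (anterior positive), z inferior-superior (superior
  positive).
* Array index order is ``(ix, iy, iz)`` matching ``(x, y, z)``.
* All physical coordinates are in millimetres; a voxel's coordinate is the
  coordinate of its *center*; indices are 0-based.
* The world origin coincides with the scanner / machine isocenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class TissueClass(IntEnum):
    """Integer tissue codes carried by a :class:`LabelMap`."""

    OUTSIDE = 0
    SOFT = 1
    BONE = 2
    AIR = 3
    TOOTH = 4
    IMPLANT = 5
    ARTIFACT = 6


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    values
        3D array indexed ``(ix, iy, iz)``.
    spacing_mm
        Voxel pitch along (x, y, z); strictly positive.
    origin_mm
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"every axis must have length >= 1, got {self.values.shape}")
        if np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if np.issubdtype(self.values.dtype, np.floating) and not np.all(
            np.isfinite(self.values)
        ):
            raise ValueError("volume values must be finite")

    # -- grid geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin_mm) / self.spacing_mm

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return self.origin_mm + idx * self.spacing_mm

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(n)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (x, y, z) for every voxel."""
        xs = self.axis_coordinates(0)[:, None, None]
        ys = self.axis_coordinates(1)[None, :, None]
        zs = self.axis_coordinates(2)[None, None, :]
        return xs, ys, zs

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )

    def like(self, values: np.ndarray) -> "Volume":
        """A new volume with the same grid and the given values."""
        if values.shape != self.shape:
            raise ValueError(f"shape {values.shape} != grid shape {self.shape}")
        return Volume(values, self.spacing_mm.copy(), self.origin_mm.copy())

    def copy(self) -> "Volume":
        return Volume(self.values.copy(), self.spacing_mm.copy(), self.origin_mm.copy())


def centered_grid(shape: tuple[int, int, int], spacing_mm) -> Volume:
    """An all-zero volume whose grid is centered on the world origin."""
    shape = tuple(int(s) for s in shape)
    spacing = np.asarray(spacing_mm, dtype=float).reshape(3)
    origin = -spacing * (np.asarray(shape) - 1) / 2.0
    return Volume(np.zeros(shape, dtype=np.float32), spacing, origin)


@dataclass
class LabelMap:
    """Integer tissue-class volume (codes from :class:`TissueClass`)."""

    volume: Volume

    def __post_init__(self) -> None:
        vals = self.volume.values
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("LabelMap values must be integer typed")
        codes = {int(c) for c in np.unique(vals)}
        allowed = {int(c) for c in TissueClass}
        if not codes <= allowed:
            raise ValueError(f"unknown label codes: {sorted(codes - allowed)}")

    def mask(self, *classes: TissueClass) -> np.ndarray:
        return np.isin(self.volume.values, [int(c) for c in classes])

    @property
    def body(self) -> np.ndarray:
        return self.volume.values != int(TissueClass.OUTSIDE)


@dataclass
class StructureSet:
    """Named binary masks sharing one reference grid.

    Conventional names: ``BODY``, ``PTV70``, ``PTV63``, ``PTV59``, OARs
    (``brainstem``, ``cord``, ``cord+5mm``, ``chiasm``, ``optic_nerve_l/r``)
    and derived implant-slab targets ``sPTV70`` / ``sPTV63``.
    """

    masks: dict[str, np.ndarray]
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks are on inconsistent grids: {shapes}")
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def as_volume(self, name: str) -> Volume:
        return Volume(self.masks[name].astype(np.uint8), self.spacing_mm, self.origin_mm)

    def copy(self) -> "StructureSet":
        return StructureSet(
            {k: v.copy() for k, v in self.masks.items()},
            self.spacing_mm.copy(),
            self.origin_mm.copy(),
        )


# Default planning prescriptions (Gy) and OAR maximum-dose caps (Gy).
PRESCRIPTIONS_GY: dict[str, float] = {"PTV70": 70.0, "PTV63": 63.0, "PTV59": 59.5}

# The 93%-of-prescription DVH levels are reported at fixed printed values,
# not recomputed from 0.93 * Rx (0.93 * 59.5 = 55.335 prints as 55).
V93_LEVELS_GY: dict[float, float] = {70.0: 65.0, 63.0: 58.6, 59.5: 55.0}

OAR_MAX_GY: dict[str, float] = {
    "brainstem": 54.0,
    "cord": 45.0,
    "cord+5mm": 50.0,
    "chiasm": 54.0,
    "optic_nerve_l": 54.0,
    "optic_nerve_r": 54.0,
}
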