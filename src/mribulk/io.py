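"""Volume, structure-set, and configuration I/O.

Volumes are stored as NIfTI-1 (the affine carries spacing on its diagonal
and the origin in its translation column; the package's patient axes map
directly onto the NIfTI i/j/k axes).  A raw-binary + JSON-header fallback
format (``.raw`` + ``.json``) is provided for environments without NIfTI
tooling.  Structure sets are one NIfTI mask per structure plus a JSON
manifest; grid-phantom truth coordinates are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .volume import StructureSet, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_structure_set",
    "write_structure_set",
    "write_landmarks_csv",
    "read_landmarks_csv",
    "load_yaml",
    "dump_yaml",
]


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii) or raw+JSON (.raw)."""
    path = Path(path)
    if path.suffix == ".raw":
        header = {
            "shape": list(vol.shape),
            "dtype": str(vol.values.dtype),
            "spacing_mm": vol.spacing_mm.tolist(),
            "origin_mm": vol.origin_mm.tolist(),
            "order": "C",
        }
        path.write_bytes(np.ascontiguousarray(vol.values).tobytes())
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))
        return path
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing_mm)
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(np.asarray(vol.values), affine)
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 or raw+JSON volume written by :func:`write_volume`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    if path.suffix == ".raw":
        hdr_path = path.with_suffix(".json")
        if not hdr_path.exists():
            raise FileNotFoundError(f"raw volume missing JSON header: {hdr_path}")
        header = json.loads(hdr_path.read_text())
        for key in ("shape", "dtype", "spacing_mm", "origin_mm"):
            if key not in header:
                raise ValueError(f"malformed raw header: missing field {key!r}")
        values = np.frombuffer(path.read_bytes(), dtype=header["dtype"]).reshape(
            header["shape"]
        )
        return Volume(values.copy(), header["spacing_mm"], header["origin_mm"])
    img = nib.load(str(path))
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    if np.any(spacing <= 0):
        raise ValueError(f"malformed NIfTI header: non-positive spacing {spacing}")
    origin = affine[:3, 3]
    values = np.asarray(img.dataobj)
    return Volume(values, spacing, origin)


def write_structure_set(structs: StructureSet, out_dir: str | Path) -> Path:
    """One NIfTI mask per structure plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name in structs.names:
        safe = name.replace("+", "plus").replace(" ", "_")
        fname = f"mask_{safe}.nii"
        write_volume(structs.as_volume(name), out_dir / fname)
        entries[name] = fname
    manifest = {
        "masks": entries,
        "spacing_mm": structs.spacing_mm.tolist(),
        "origin_mm": structs.origin_mm.tolist(),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_structure_set(manifest_path: str | Path) -> StructureSet:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"no such manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    masks = {}
    for name, fname in manifest["masks"].items():
        vol = read_volume(manifest_path.parent / fname)
        masks[name] = vol.values.astype(bool)
    return StructureSet(masks, manifest["spacing_mm"], manifest["origin_mm"])


def write_landmarks_csv(points_mm: np.ndarray, path: str | Path, z_mm: float = 0.0) -> Path:
    path = Path(path)
    pts = np.atleast_2d(points_mm)
    df = pd.DataFrame(
        {
            "x_mm": pts[:, 0],
            "y_mm": pts[:, 1],
            "z_mm": pts[:, 2] if pts.shape[1] > 2 else np.full(len(pts), z_mm),
        }
    )
    df.to_csv(path, index=False)
    return path


def read_landmarks_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
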