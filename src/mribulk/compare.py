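"""Dose-volume histograms, coverage statistics, and plan comparison.

Coverage is summarized by V100% and V93%: the percentage of a structure's
volume receiving at least 100 % / 93 % of its prescription.  ``Vx`` uses
the inclusive convention (dose >= level counts, matching the "should
receive" phrasing of the planning constraints), and the 93 % levels are
the fixed printed values 65 / 58.6 / 55 Gy for the 70 / 63 / 59.5 Gy
prescriptions rather than recomputed products.

Differences between a predicted dose (the bulk-density plan evaluated on
its own density) and the actual dose (the same monitor units forward-
calculated on heterogeneity-corrected CT) are reported as
``predicted - actual`` in percentage points of structure volume, so a
negative difference signifies a smaller volume on the MRI-based side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import OAR_MAX_GY, V93_LEVELS_GY, StructureSet, Volume

__all__ = [
    "DVHCurve",
    "CoverageReport",
    "compute_dvh",
    "coverage_metrics",
    "coverage_difference",
    "dose_difference_map",
    "constraint_report",
    "v93_level",
]


def v93_level(rx_gy: float) -> float:
    """The 93 %-of-prescription DVH level (printed planning values)."""
    return V93_LEVELS_GY.get(float(rx_gy), 0.93 * rx_gy)


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``fraction[i]`` is the fraction of structure volume receiving at least
    ``edges_gy[i]``; the curve starts at 1.0 for 0 Gy, is monotone
    non-increasing, and its last edge exceeds the maximum structure dose.
    """

    structure: str
    edges_gy: np.ndarray
    fraction: np.ndarray
    volume_cc: float = float("nan")

    def value_at(self, dose_gy: float) -> float:
        """Fractional volume receiving >= ``dose_gy`` (step interpolation).

        Evaluated from the stored cumulative bins: the fraction at the
        largest edge <= the query dose.
        """
        i = int(np.searchsorted(self.edges_gy, dose_gy, side="right")) - 1
        if i < 0:
            return 1.0
        if i >= len(self.fraction):
            return 0.0
        return float(self.fraction[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.edges_gy, "fraction": self.fraction})


def compute_dvh(
    dose: Volume | np.ndarray,
    struct: np.ndarray,
    bin_gy: float = 0.1,
    name: str = "",
    voxel_volume_mm3: float | None = None,
) -> DVHCurve:
    """Cumulative DVH of a structure (uniform-grid exact voxel counting)."""
    if bin_gy <= 0:
        raise ValueError("bin width must be > 0")
    struct = np.asarray(struct, dtype=bool)
    if isinstance(dose, Volume):
        vals = dose.values
        if voxel_volume_mm3 is None:
            voxel_volume_mm3 = dose.voxel_volume_mm3
    else:
        vals = np.asarray(dose)
    if vals.shape != struct.shape:
        raise ValueError("dose and structure must share the grid")
    d = vals[struct]
    if d.size == 0:
        raise ValueError(f"structure {name!r} is empty")
    n_bins = int(np.floor(d.max() / bin_gy)) + 2
    edges = bin_gy * np.arange(n_bins)
    # fraction receiving >= edge: count of voxels with dose >= edge
    counts = np.searchsorted(np.sort(d), edges, side="left")
    frac = 1.0 - counts / d.size
    vol_cc = d.size * (voxel_volume_mm3 or float("nan")) / 1000.0
    return DVHCurve(structure=name, edges_gy=edges, fraction=frac, volume_cc=vol_cc)


def coverage_metrics(dvh: DVHCurve, rx_gy: float) -> tuple[float, float]:
    """(V100, V93) in percent of structure volume for a prescription."""
    if rx_gy <= 0:
        raise ValueError("prescription must be positive")
    v100 = 100.0 * dvh.value_at(rx_gy)
    v93 = 100.0 * dvh.value_at(v93_level(rx_gy))
    return v100, v93


@dataclass
class CoverageReport:
    """Per-structure predicted/actual coverage and their differences.

    ``table`` columns: structure, rx_gy, V100_pred, V100_act, dV100,
    V93_pred, V93_act, dV93 — differences are predicted - actual in
    percentage points.
    """

    table: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """Mean +- standard error of the mean of the differences."""
        n = len(self.table)
        out = {}
        for col in ("dV100", "dV93"):
            vals = self.table[col].to_numpy(dtype=float)
            sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            out[col] = {"mean": vals.mean(), "sem": sem, "n": n}
        return pd.DataFrame(out)

    def row(self, structure: str) -> pd.Series:
        return self.table.set_index("structure").loc[structure]


def coverage_difference(
    predicted: Volume | np.ndarray,
    actual: Volume | np.ndarray,
    structs: StructureSet | dict[str, np.ndarray],
    prescriptions_gy: dict[str, float],
    bin_gy: float = 0.1,
) -> CoverageReport:
    """Coverage differences (predicted - actual) per prescribed structure."""
    masks = structs.masks if isinstance(structs, StructureSet) else structs
    pv = predicted.values if isinstance(predicted, Volume) else np.asarray(predicted)
    av = actual.values if isinstance(actual, Volume) else np.asarray(actual)
    if pv.shape != av.shape:
        raise ValueError("predicted and actual doses must share the grid")
    rows = []
    for name, rx in prescriptions_gy.items():
        if name not in masks:
            raise KeyError(f"prescribed structure {name!r} missing from the set")
        m = masks[name]
        dvh_p = compute_dvh(pv, m, bin_gy, name)
        dvh_a = compute_dvh(av, m, bin_gy, name)
        v100p, v93p = coverage_metrics(dvh_p, rx)
        v100a, v93a = coverage_metrics(dvh_a, rx)
        rows.append(
            {
                "structure": name,
                "rx_gy": rx,
                "V100_pred": v100p,
                "V100_act": v100a,
                "dV100": v100p - v100a,
                "V93_pred": v93p,
                "V93_act": v93a,
                "dV93": v93p - v93a,
            }
        )
    return CoverageReport(table=pd.DataFrame(rows))


def dose_difference_map(
    dose_a: Volume,
    dose_b: Volume,
    thresholds_gy: tuple[float, ...] = (1.0, 2.0, 3.0),
    region: np.ndarray | None = None,
) -> Volume:
    """Label voxels by the highest exceeded absolute-difference threshold.

    Label k (1-based) means ``|dose_a - dose_b|`` exceeds
    ``thresholds_gy[k-1]`` (strictly); label 0 means below every
    threshold or outside the region of interest.
    """
    th = np.asarray(thresholds_gy, dtype=float)
    if np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if not dose_a.same_grid(dose_b):
        raise ValueError("dose volumes must share the grid")
    diff = np.abs(dose_a.values - dose_b.values)
    labels = np.zeros(diff.shape, dtype=np.int16)
    for i, t in enumerate(th, start=1):
        labels[diff > t] = i
    if region is not None:
        labels[~np.asarray(region, dtype=bool)] = 0
    return Volume(labels, dose_a.spacing_mm.copy(), dose_a.origin_mm.copy())


def constraint_report(
    dose: Volume,
    structs: StructureSet,
    oar_max_gy: dict[str, float] | None = None,
    prescriptions_gy: dict[str, float] | None = None,
    bin_gy: float = 0.1,
) -> pd.DataFrame:
    """Planning-constraint pass/fail table.

    OARs pass when their maximum voxel dose is <= the cap (inclusive);
    PTVs pass when V100 >= 95 % and V93 >= 99 %.
    """
    oar_max_gy = OAR_MAX_GY if oar_max_gy is None else oar_max_gy
    rows = []
    for name, cap in oar_max_gy.items():
        if name not in structs or not structs[name].any():
            continue
        dmax = float(dose.values[structs[name]].max())
        rows.append(
            {
                "structure": name,
                "kind": "OAR",
                "metric": "max_gy",
                "value": dmax,
                "limit": cap,
                "passed": dmax <= cap,
            }
        )
    if prescriptions_gy:
        for name, rx in prescriptions_gy.items():
            if name not in structs or not structs[name].any():
                continue
            dvh = compute_dvh(dose, structs[name], bin_gy, name)
            v100, v93 = coverage_metrics(dvh, rx)
            rows.append(
                {
                    "structure": name,
                    "kind": "PTV",
                    "metric": "V100_pct",
                    "value": v100,
                    "limit": 95.0,
                    "passed": v100 >= 95.0,
                }
            )
            rows.append(
                {
                    "structure": name,
                    "kind": "PTV",
                    "metric": "V93_pct",
                    "value": v93,
                    "limit": 99.0,
                    "passed": v93 >= 99.0,
                }
            )
    return pd.DataFrame(rows)
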