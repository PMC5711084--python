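"""End-to-end bulk-density planning experiment on a synthetic cohort.

For each synthetic patient: generate the paired pseudo-CT / pseudo-MRI
head phantom; build the heterogeneity-corrected CT density and the three
bulk-density volumes (W, W+B, W+B+A); crop structures to the standardized
contours; inverse-optimize a seven-field plan on each bulk scheme's own
density; freeze the monitor units and forward-recalculate on the CT
density; and tabulate V100%/V93% coverage differences (predicted -
actual), implant-slab sub-targets, constraint reports, and dose-difference
maps.  The cohort report aggregates differences as mean +- standard error
of the mean.  Everything is a pure function of the configuration
(per-patient seeds drive phantom jitter and optimizer initialisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import (
    CoverageReport,
    constraint_report,
    coverage_difference,
    dose_difference_map,
)
from .density import (
    BulkScheme,
    CalibrationCurve,
    build_ct_density,
    build_density_scheme,
    crop_structures,
    extract_sptv,
    segment_by_threshold,
)
from .dose import (
    BeamSpec,
    EngineModel,
    Objectives,
    Plan,
    compute_dose_at_points,
    default_beam_angles,
    forward_recalculate,
    optimize_fluence,
)
from .phantoms import HeadPhantomConfig, make_head_phantom
from .volume import OAR_MAX_GY, PRESCRIPTIONS_GY, StructureSet, TissueClass, Volume

logger = logging.getLogger("mribulk")

__all__ = ["ExperimentConfig", "PatientResult", "ExperimentResult", "run_experiment"]

SCHEMES = ("W", "W+B", "W+B+A")


@dataclass
class ExperimentConfig:
    """Configuration of the three-scheme comparison experiment."""

    phantom: HeadPhantomConfig = field(default_factory=HeadPhantomConfig)
    schemes: tuple[str, ...] = SCHEMES
    seeds: tuple[int, ...] = (1,)
    engine: EngineModel = field(default_factory=EngineModel)
    n_iterations: int = 200
    beam_angles_deg: tuple[float, ...] = field(default_factory=default_beam_angles)
    n_u: int = 20
    n_v: int = 20
    beamlet_mm: float = 5.0
    inner_margin_mm: float = 5.0
    inferior_cut_mm: float | None = -70.0
    internal_extra_mm: float = 10.0
    prescriptions_gy: dict[str, float] = field(
        default_factory=lambda: dict(PRESCRIPTIONS_GY)
    )
    oar_max_gy: dict[str, float] = field(default_factory=lambda: dict(OAR_MAX_GY))
    compute_difference_maps: bool = False
    # Evaluate sPTV rows over this fixed z-range (mm) when no implants are
    # present, enabling like-for-like implant vs implant-free slab
    # comparisons on the same axial slices.
    sptv_slab_z: tuple[float, float] | None = None
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one scheme required")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("per-patient seeds must be distinct")


@dataclass
class PatientResult:
    """Per-patient coverage tables and artifacts."""

    seed: int
    coverage: dict[str, CoverageReport]  # scheme -> report (incl. sPTV rows)
    constraints: dict[str, pd.DataFrame]
    difference_map_counts: dict[str, dict[int, int]] = field(default_factory=dict)
    error: str | None = None


@dataclass
class ExperimentResult:
    """Cohort report: per-patient results plus aggregated differences."""

    config: ExperimentConfig
    patients: list[PatientResult]
    cohort_table: pd.DataFrame  # rows: (patient, scheme, structure, dV100, dV93)

    def aggregate(self) -> pd.DataFrame:
        """Mean +- SEM of dV100/dV93 per scheme and structure."""
        g = self.cohort_table.groupby(["scheme", "structure"])
        agg = g.agg(
            dV100_mean=("dV100", "mean"),
            dV100_sem=("dV100", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
            dV93_mean=("dV93", "mean"),
            dV93_sem=("dV93", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
            n=("dV100", "size"),
        )
        return agg.reset_index()

    def scheme_mean(self, scheme: str, structure: str = "PTV70", col: str = "dV100") -> float:
        t = self.cohort_table
        sel = t[(t["scheme"] == scheme) & (t["structure"] == structure)]
        return float(sel[col].mean())


def _mask_points(structs: StructureSet, mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return structs.origin_mm + idx * structs.spacing_mm


def _dose_array_at(
    plan: Plan, red: Volume, model: EngineModel, structs: StructureSet, union: np.ndarray
) -> np.ndarray:
    """Dose values filled into a volume-shaped array at the union mask."""
    pts = _mask_points(structs, union)
    dose = np.zeros(union.shape)
    dose[union] = compute_dose_at_points(plan, red, model, pts)
    return dose


def run_patient(cfg: ExperimentConfig, seed: int) -> PatientResult:
    """Run the full per-patient pipeline for one seed."""
    labels, ct, _mri, structs = make_head_phantom(cfg.phantom, seed=seed)
    body = structs["BODY"]

    # Segmentation (on CT, as the standardized-contour workflow does) and
    # densities.  Artifact voxels corrupt thresholds, so masks for the
    # bulk schemes come from threshold segmentation while implant/artifact
    # masks come from the (manually contoured) truth.
    bone_seg, air_seg = segment_by_threshold(ct, body=body)
    implant_mask = labels.mask(TissueClass.IMPLANT)
    artifact_mask = labels.mask(TissueClass.ARTIFACT)
    bone_seg &= ~implant_mask  # implants are contoured separately on CT

    curve = CalibrationCurve()
    red_ct = build_ct_density(
        ct, body, curve,
        implant_mask=implant_mask if implant_mask.any() else None,
        artifact_mask=artifact_mask if artifact_mask.any() else None,
    )
    masks = {"bone": bone_seg & ~artifact_mask, "air": air_seg & ~artifact_mask}

    structs_c = crop_structures(
        structs, body, cfg.inner_margin_mm, cfg.inferior_cut_mm, cfg.internal_extra_mm
    )
    slab_mask = implant_mask
    if not slab_mask.any() and cfg.sptv_slab_z is not None:
        zs = np.arange(body.shape[2]) * structs.spacing_mm[2] + structs.origin_mm[2]
        z0, z1 = cfg.sptv_slab_z
        slab_mask = np.zeros_like(body)
        slab_mask[:, :, (zs >= z0) & (zs <= z1)] = True
    if slab_mask.any():
        for tgt in ("PTV70", "PTV63"):
            structs_c.masks[f"s{tgt}"] = extract_sptv(structs_c[tgt], slab_mask)

    prescriptions = {
        k: v for k, v in cfg.prescriptions_gy.items()
        if k in structs_c and structs_c[k].any()
    }
    eval_names = list(prescriptions) + [
        n for n in ("sPTV70", "sPTV63") if n in structs_c and structs_c[n].any()
    ]
    union = np.zeros_like(body)
    for n in eval_names + [n for n in cfg.oar_max_gy if n in structs_c]:
        union |= structs_c[n]

    skeleton = Plan(
        [
            BeamSpec(
                gantry_angle_deg=a, n_u=cfg.n_u, n_v=cfg.n_v, beamlet_mm=cfg.beamlet_mm
            )
            for a in cfg.beam_angles_deg
        ],
        prescriptions_gy=prescriptions,
    )
    objectives = Objectives(
        target_rx_gy=prescriptions,
        oar_max_gy={k: v for k, v in cfg.oar_max_gy.items() if k in structs_c},
    )

    coverage: dict[str, CoverageReport] = {}
    constraints: dict[str, pd.DataFrame] = {}
    diff_counts: dict[str, dict[int, int]] = {}
    eval_prescriptions = dict(prescriptions)
    if "sPTV70" in structs_c and structs_c["sPTV70"].any():
        eval_prescriptions["sPTV70"] = prescriptions.get("PTV70", 70.0)
    if "sPTV63" in structs_c and structs_c["sPTV63"].any():
        eval_prescriptions["sPTV63"] = prescriptions.get("PTV63", 63.0)

    for scheme in cfg.schemes:
        logger.info("seed %d: optimizing scheme %s", seed, scheme)
        red_scheme = build_density_scheme(
            masks, body, BulkScheme(scheme),
            implant_mask=implant_mask if implant_mask.any() else None,
            spacing_mm=structs.spacing_mm, origin_mm=structs.origin_mm,
        )
        result = optimize_fluence(
            skeleton, structs_c, red_scheme, objectives, cfg.engine,
            seed=seed, n_iterations=cfg.n_iterations,
        )
        predicted = _dose_array_at(result.plan, red_scheme, cfg.engine, structs_c, union)
        actual = _dose_array_at(result.plan, red_ct, cfg.engine, structs_c, union)
        coverage[scheme] = coverage_difference(
            predicted, actual, structs_c, eval_prescriptions
        )
        dose_vol = Volume(actual, structs.spacing_mm, structs.origin_mm)
        constraints[scheme] = constraint_report(
            dose_vol, structs_c, cfg.oar_max_gy, prescriptions
        )
        if cfg.compute_difference_maps and "sPTV63" in structs_c:
            from scipy import ndimage as _ndi

            region = (
                _ndi.distance_transform_edt(
                    ~structs_c["sPTV63"], sampling=structs.spacing_mm
                )
                <= 20.0
            )
            pred_v = Volume(predicted, structs.spacing_mm, structs.origin_mm)
            # doses only known on the union mask; restrict the map there
            dmap = dose_difference_map(pred_v, dose_vol, region=region & union)
            vals, cnts = np.unique(dmap.values, return_counts=True)
            diff_counts[scheme] = {int(v): int(c) for v, c in zip(vals, cnts)}

    return PatientResult(
        seed=seed, coverage=coverage, constraints=constraints,
        difference_map_counts=diff_counts,
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Run the cohort experiment; deterministic per configuration."""
    patients: list[PatientResult] = []
    rows = []
    for seed in cfg.seeds:
        try:
            pr = run_patient(cfg, seed)
        except Exception as exc:  # a failed patient is logged, not fatal
            logger.exception("patient seed %d failed", seed)
            patients.append(
                PatientResult(seed=seed, coverage={}, constraints={}, error=str(exc))
            )
            continue
        patients.append(pr)
        for scheme, rep in pr.coverage.items():
            for _, r in rep.table.iterrows():
                rows.append(
                    {
                        "patient_seed": seed,
                        "scheme": scheme,
                        "structure": r["structure"],
                        "V100_pred": r["V100_pred"],
                        "V100_act": r["V100_act"],
                        "dV100": r["dV100"],
                        "dV93": r["dV93"],
                    }
                )
    table = pd.DataFrame(rows)
    result = ExperimentResult(config=cfg, patients=patients, cohort_table=table)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tmp = out / ".cohort_table.tmp.csv"
        table.to_csv(tmp, index=False)
        tmp.rename(out / "cohort_table.csv")
        result.aggregate().to_csv(out / "cohort_aggregate.csv", index=False)
    return result
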