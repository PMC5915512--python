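"""End-to-end seeded pipeline: generate -> classify -> change -> thresholds
-> grid -> power -> contrasts, with CSV/NIfTI artifacts and a validated
JSON report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import change as change_mod
from . import contrasts as contrasts_mod
from . import grid as grid_mod
from . import power as power_mod
from . import sigmoid as sigmoid_mod
from .change import AVERAGED_CLUSTER, roi_change_table, voxel_change_map
from .cohort import (
    AD_SIGNATURE_ROIS,
    CONTROL_ROIS,
    CohortConfig,
    ImageConfig,
    generate_cohort,
    generate_volume_pairs,
    write_cohort,
)
from .groups import PRECLINICAL, ThresholdSet, classify_cohort, summarize_groups
from .power import PowerParams

log = logging.getLogger("predecline")

__all__ = ["RunConfig", "run_pipeline", "write_report", "Report"]


@dataclass(frozen=True)
class StageToggles:
    classify: bool = True
    thresholds: bool = True
    grid: bool = True
    power: bool = True
    voxel: bool = False  # voxel-wise maps are optional (slower, bulky)
    contrasts: bool = True


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    power: PowerParams = field(default_factory=PowerParams)
    image: ImageConfig = field(default_factory=ImageConfig)
    ad_rois: tuple[str, ...] = AD_SIGNATURE_ROIS
    control_rois: tuple[str, ...] = CONTROL_ROIS
    min_tail: int = 5
    min_cell: int = 3
    stages: StageToggles = field(default_factory=StageToggles)

    def validate(self) -> None:
        self.thresholds.validate()
        self.power.validate()
        for s in self.cohort.strata:
            s.validate()
        rois = set(self.cohort.decline.roi_max_decline)
        unknown = [r for r in (*self.ad_rois, *self.control_rois) if r not in rois]
        if unknown:
            raise ValueError(f"ROIs not present in the cohort config: {unknown}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# --- report schema (pydantic models double as the published schema) ----


class ThresholdSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    biomarker: str
    c: float
    ci95: tuple[float, float]
    extrapolated: bool
    r_squared: float
    preferred_model: str
    prob_correct: float


class Report(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    config_hash: str
    status: str
    n_subjects: int | None = None
    group_counts: dict[str, int] | None = None
    above_proposed: int | None = None
    amyloid_positive_fraction: float | None = None
    thresholds: list[ThresholdSection] | None = None
    grid_n_cells: int | None = None
    power: list[dict] | None = None
    voxel_power_min_n: float | None = None
    contrasts_n_tests: int | None = None
    failures: list[str] = []


def write_report(results: dict, path=None) -> dict:
    """Validate the aggregated results against the report schema and
    (optionally) write them as JSON; returns the validated document."""
    report = Report(**results)
    doc = report.model_dump(mode="json")
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc


def _cluster_change(cohort: pd.DataFrame, ad_rois) -> tuple[pd.DataFrame, np.ndarray]:
    table = roi_change_table(cohort, cluster_rois=tuple(ad_rois))
    q = (
        table[table.roi == AVERAGED_CLUSTER]
        .set_index("subject_id")["q_value"]
        .loc[cohort["subject_id"]]
        .to_numpy()
    )
    return table, q


def run_pipeline(config: RunConfig | None = None, outdir=None) -> dict:
    """Run every enabled stage and return the validated report document.

    Artifacts (cohort CSV + config sidecar, classification summary,
    threshold fits, grid CSV, power tables, contrast tables and optional
    NIfTI volumes) are written under ``outdir`` when given.
    """
    config = config or RunConfig()
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    results: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "status": "ok",
        "failures": [],
    }

    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(cohort_cfg)
    results["n_subjects"] = len(cohort)
    if out is not None:
        write_cohort(cohort, out / "cohort.csv", out / "cohort_config.json")

    labelled = cohort
    if config.stages.classify:
        labelled = classify_cohort(cohort, config.thresholds)
        summary = summarize_groups(cohort, config.thresholds)
        results["group_counts"] = summary["counts"]
        results["above_proposed"] = summary["above_proposed"]
        results["amyloid_positive_fraction"] = summary["amyloid_positive_fraction"]
        if out is not None:
            labelled.to_csv(out / "cohort_classified.csv", index=False)
            (out / "group_summary.json").write_text(json.dumps(summary, indent=2))

    change_table, q_cluster = _cluster_change(cohort, config.ad_rois)
    if out is not None:
        change_table.to_csv(out / "change_table.csv", index=False)

    if config.stages.thresholds:
        sections = []
        for biomarker, col in (("florbetapir_suvr", "florbetapir_suvr"),
                               ("csf_ptau", "csf_ptau")):
            try:
                res = sigmoid_mod.threshold_analysis(
                    cohort[col].to_numpy(),
                    q_cluster,
                    min_tail=config.min_tail,
                    biomarker=biomarker,
                )
            except Exception as exc:
                results["failures"].append(f"thresholds/{biomarker}: {exc}")
                results["status"] = "partial"
                continue
            est = res["estimate"]
            if est is None:
                results["failures"].append(f"thresholds/{biomarker}: fit not converged")
                results["status"] = "partial"
                continue
            sections.append(
                {
                    "biomarker": biomarker,
                    "c": est.c,
                    "ci95": est.ci95,
                    "extrapolated": est.extrapolated,
                    "r_squared": res["sigmoid"].r_squared,
                    "preferred_model": res["comparison"].preferred,
                    "prob_correct": res["comparison"].prob_correct,
                }
            )
            if out is not None:
                res["curve"].to_frame().to_csv(
                    out / f"curve_{biomarker}.csv", index=False
                )
        results["thresholds"] = sections

    if config.stages.grid:
        grid = grid_mod.build_threshold_grid(
            cohort["florbetapir_suvr"].to_numpy(),
            cohort["csf_ptau"].to_numpy(),
            q_cluster,
            thresholds=config.thresholds,
            min_cell=config.min_cell,
        )
        results["grid_n_cells"] = grid.n_cells
        if out is not None:
            grid.to_frame().to_csv(out / "threshold_grid.csv", index=False)

    if config.stages.power and config.stages.classify:
        groups = pd.Series(
            np.where(
                labelled["above_proposed"],
                "above-proposed",
                np.where(labelled["group"] == PRECLINICAL, "preclinical-standard",
                         "other"),
            ),
            index=labelled["subject_id"],
        )
        whole = pd.Series("whole-cohort", index=labelled["subject_id"])
        tables = []
        for name, grp in (("enrichment", groups), ("whole", whole)):
            try:
                tab = power_mod.roi_power_table(change_table, grp, config.power)
                tab.insert(0, "scheme", name)
                tables.append(tab)
            except ValueError as exc:
                results["failures"].append(f"power/{name}: {exc}")
                results["status"] = "partial"
        if tables:
            power_tab = pd.concat(tables, ignore_index=True)
            results["power"] = power_tab.to_dict(orient="records")
            if out is not None:
                power_tab.to_csv(out / "power_table.csv", index=False)

    if config.stages.voxel:
        results.update(_voxel_stage(cohort, labelled, config, out))

    if config.stages.contrasts and config.stages.classify:
        contrast_cohort = labelled.copy()
        contrast_cohort.loc[contrast_cohort["above_proposed"], "group"] = (
            "preclinical-above"
        )
        res = contrasts_mod.ancova_contrast(change_table, contrast_cohort)
        results["contrasts_n_tests"] = len(res)
        if out is not None:
            contrasts_mod.contrasts_to_frame(res).to_csv(
                out / "contrasts.csv", index=False
            )
            demo = contrasts_mod.demographics_table(contrast_cohort)
            (out / "demographics.json").write_text(json.dumps(demo, indent=2))

    report = write_report(
        results, out / "report.json" if out is not None else None
    )
    return report


def _voxel_stage(cohort, labelled, config: RunConfig, out) -> dict:
    """Voxel-wise change maps, FDR mask and sample-size map for the
    above-proposed group."""
    sel = labelled[labelled["above_proposed"]]
    if len(sel) < 3:
        return {"failures": ["voxel: fewer than 3 above-proposed subjects"],
                "status": "partial"}
    pairs = generate_volume_pairs(sel, config.image, seed=config.seed + 1)
    maps = []
    for pair, (_, row) in zip(pairs, sel.iterrows()):
        vol, _ = voxel_change_map(pair, row["followup_months"])
        maps.append(vol)
    stats_d = power_mod.voxel_decline_stats(np.asarray(maps))
    mask = power_mod.fdr_mask(stats_d["p"], config.power.fdr_q)
    pmap = power_mod.sample_size_map(stats_d, mask, config.power)
    if out is not None:
        from .io_nifti import write_volume

        affine = np.diag([config.image.voxel_size] * 3 + [1.0])
        write_volume(stats_d["mean"], affine, out / "voxel_mean_change.nii")
        write_volume(stats_d["p"], affine, out / "voxel_p.nii")
        write_volume(mask.astype(np.uint8), affine, out / "voxel_fdr_mask.nii")
        write_volume(pmap.n_per_arm, affine, out / "voxel_n_per_arm.nii")
        summary = power_mod.roi_summary_from_map(
            pmap, pairs[0].labels, pairs[0].roi_ids
        )
        summary.to_csv(out / "voxel_power_rois.csv", index=False)
    return {"voxel_power_min_n": pmap.minimum()}
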