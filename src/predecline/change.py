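"""Annualized percent-change statistic for ROI panels and voxel volumes.

The change statistic is

    Q = ((SUVR_followup - SUVR_baseline) / SUVR_baseline) * 100 / dt

with ``dt`` the follow-up interval in years, i.e. percent change per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AD_SIGNATURE_ROIS, VolumePair

__all__ = [
    "AVERAGED_CLUSTER",
    "annualized_change",
    "roi_change_table",
    "voxel_change_map",
    "roi_means_from_map",
]

#: Pseudo-ROI name for the mean change over the AD-signature cluster.
AVERAGED_CLUSTER = "averaged_cluster"


def annualized_change(baseline, followup, delta_months):
    """Percent change per year between baseline and follow-up.

    All arguments may be scalars or broadcastable arrays; baseline and the
    follow-up interval must be strictly positive.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    delta_months = np.asarray(delta_months, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be > 0")
    if np.any(delta_months <= 0):
        raise ValueError("delta_months must be > 0")
    out = (followup - baseline) / baseline * 100.0 / (delta_months / 12.0)
    return out.item() if out.ndim == 0 else out


def roi_change_table(
    cohort: pd.DataFrame,
    rois: list[str] | None = None,
    cluster_rois: tuple[str, ...] = AD_SIGNATURE_ROIS,
) -> pd.DataFrame:
    """Long table of per-subject, per-ROI annualized change.

    One row per subject x ROI with columns ``subject_id, roi, q_value``,
    plus a row per subject for the averaged cluster (mean of the change
    values over ``cluster_rois``).
    """
    if rois is None:
        rois = list(cohort.attrs.get("rois", []))
        if not rois:
            rois = [
                c[: -len("_baseline")] for c in cohort.columns if c.endswith("_baseline")
            ]
    missing = [
        f"{roi}_{suffix}"
        for roi in rois
        for suffix in ("baseline", "followup")
        if f"{roi}_{suffix}" not in cohort.columns
    ]
    if missing:
        raise ValueError(f"cohort is missing ROI columns: {missing}")
    dt = cohort["followup_months"].to_numpy(dtype=float)
    rows = []
    per_roi = {}
    for roi in rois:
        q = annualized_change(
            cohort[f"{roi}_baseline"].to_numpy(dtype=float),
            cohort[f"{roi}_followup"].to_numpy(dtype=float),
            dt,
        )
        q = np.atleast_1d(q)
        per_roi[roi] = q
        rows.append(
            pd.DataFrame(
                {"subject_id": cohort["subject_id"], "roi": roi, "q_value": q}
            )
        )
    cluster = [r for r in cluster_rois if r in rois]
    if cluster:
        q_cluster = np.mean([per_roi[r] for r in cluster], axis=0)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "roi": AVERAGED_CLUSTER,
                    "q_value": q_cluster,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["subject_id", "roi", "q_value"])
    return pd.concat(rows, ignore_index=True)


def voxel_change_map(
    pair: VolumePair, delta_months: float
) -> tuple[np.ndarray, int]:
    """Per-voxel annualized change; background voxels are NaN.

    Returns ``(change_volume, n_flagged)`` where ``n_flagged`` counts
    in-mask voxels whose baseline was nonpositive (set to NaN).
    """
    if delta_months <= 0:
        raise ValueError("delta_months must be > 0")
    if pair.baseline.shape != pair.followup.shape or (
        pair.baseline.shape != pair.labels.shape
    ):
        raise ValueError("baseline, follow-up and label volumes must share shape")
    mask = pair.labels > 0
    out = np.full(pair.baseline.shape, np.nan)
    base = pair.baseline
    bad = mask & (base <= 0)
    ok = mask & (base > 0)
    out[ok] = (
        (pair.followup[ok] - base[ok]) / base[ok] * 100.0 / (delta_months / 12.0)
    )
    return out, int(bad.sum())


def roi_means_from_map(
    change_map: np.ndarray, labels: np.ndarray, roi_ids: dict[str, int]
) -> dict[str, float]:
    """Mean of a change map over each labelled ROI (NaN voxels ignored)."""
    if change_map.shape != labels.shape:
        raise ValueError("change map and label volume must share shape")
    return {
        roi: float(np.nanmean(change_map[labels == lab]))
        for roi, lab in roi_ids.items()
    }
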