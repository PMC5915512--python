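"""Per-arm sample-size formula and voxel-wise / ROI power analysis.

The per-arm sample size to detect a fractional drug effect ``beta`` on the
mean annualized change ``delta_mu`` with SD ``sigma`` is

    n = (power_coef + sig_coef)^2 * 2 * sigma^2 / (delta_mu * beta)^2

with the conventional coefficients 0.842 (80% power) and 1.96 (two-sided
5% significance), rounded up to the next whole subject. Voxel-wise, the
same formula is applied at every voxel showing a significant decline
after Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PowerParams",
    "PowerMap",
    "per_arm_sample_size",
    "invert_sample_size",
    "voxel_decline_stats",
    "fdr_mask",
    "sample_size_map",
    "roi_summary_from_map",
    "roi_power_table",
]


@dataclass(frozen=True)
class PowerParams:
    """Coefficients of the sample-size formula and the FDR level."""

    power_coef: float = 0.842  # one-sided quantile for 80% power
    sig_coef: float = 1.96  # two-sided quantile for 5% significance
    effect: float = 0.25  # fractional drug effect on the mean change
    fdr_q: float = 0.001

    def validate(self) -> None:
        if self.power_coef <= 0 or self.sig_coef <= 0:
            raise ValueError("power_coef and sig_coef must be positive")
        if not 0.0 < self.effect <= 1.0:
            raise ValueError("effect must lie in (0, 1]")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")


def per_arm_sample_size(delta_mu, sigma, params: PowerParams | None = None):
    """Subjects per trial arm; ceiling rounding, floored at 1.

    ``delta_mu`` is the magnitude of the expected mean change (its sign is
    ignored) and must be nonzero; ``sigma`` is the SD of the change.
    Scalars or arrays (returns an integer array with -1 never produced;
    invalid entries raise).
    """
    p = params or PowerParams()
    p.validate()
    dm = np.abs(np.asarray(delta_mu, dtype=float))
    sg = np.asarray(sigma, dtype=float)
    if np.any(dm == 0):
        raise ValueError("delta_mu = 0: enrichment target undefined")
    if np.any(sg < 0):
        raise ValueError("sigma must be >= 0")
    raw = (p.power_coef + p.sig_coef) ** 2 * 2.0 * sg**2 / (dm * p.effect) ** 2
    n = np.maximum(np.ceil(raw), 1.0)
    return int(n) if n.ndim == 0 else n.astype(int)


def invert_sample_size(n: int, params: PowerParams | None = None) -> float:
    """The sigma/delta_mu ratio at which the formula returns ``n``."""
    p = params or PowerParams()
    p.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    return p.effect * math.sqrt(n / 2.0) / (p.power_coef + p.sig_coef)


def voxel_decline_stats(change_maps) -> dict[str, np.ndarray]:
    """Per-voxel one-sample two-sided t-test of mean change against zero.

    ``change_maps`` stacks one change volume per subject (list or 4-D
    array, subject axis first). A voxel that is missing (NaN) in any
    subject, or whose across-subject SD is zero, is flagged and reported
    as missing in the test outputs.
    """
    data = np.asarray(change_maps, dtype=float)
    if data.ndim < 2:
        raise ValueError("need a subject axis plus at least one spatial axis")
    n_subj = data.shape[0]
    if n_subj < 3:
        raise ValueError(f"need at least 3 subjects, got {n_subj}")
    valid = np.isfinite(data).all(axis=0)
    mean = np.full(data.shape[1:], np.nan)
    sd = np.full(data.shape[1:], np.nan)
    mean[valid] = data[:, valid].mean(axis=0)
    sd[valid] = data[:, valid].std(axis=0, ddof=1)
    testable = valid & (sd > 0)
    t = np.full(data.shape[1:], np.nan)
    p = np.full(data.shape[1:], np.nan)
    t[testable] = mean[testable] / (sd[testable] / math.sqrt(n_subj))
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), n_subj - 1)
    return {
        "mean": mean,
        "sd": sd,
        "t": t,
        "p": p,
        "n_subjects": n_subj,
        "degenerate": valid & (sd == 0),
    }


def fdr_mask(p_values: np.ndarray, q: float = 0.001) -> np.ndarray:
    """Benjamini-Hochberg rejection mask over non-missing p-values."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    mask = np.zeros(p.shape, dtype=bool)
    if finite.any():
        reject, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        mask[finite] = reject
    return mask


@dataclass
class PowerMap:
    """Voxel-wise decline statistics with the FDR mask and per-arm n."""

    mean_change: np.ndarray
    sd_change: np.ndarray
    p_value: np.ndarray
    fdr_mask: np.ndarray
    n_per_arm: np.ndarray  # float volume, NaN where unmasked
    params: PowerParams
    status: str = "ok"

    def minimum(self) -> float:
        """Smallest per-arm n over masked voxels (NaN if the mask is empty)."""
        if not np.isfinite(self.n_per_arm).any():
            return math.nan
        return float(np.nanmin(self.n_per_arm))


def sample_size_map(
    stats_dict: dict[str, np.ndarray],
    mask: np.ndarray,
    params: PowerParams | None = None,
) -> PowerMap:
    """Per-arm sample size at every masked voxel.

    ``stats_dict`` is the output of :func:`voxel_decline_stats`; ``mask``
    is typically its FDR mask. Voxels outside the mask, or with zero mean
    change, carry NaN.
    """
    p = params or PowerParams()
    p.validate()
    mean = stats_dict["mean"]
    sd = stats_dict["sd"]
    if mask.shape != mean.shape:
        raise ValueError("mask and statistics volumes must share shape")
    n = np.full(mean.shape, np.nan)
    usable = mask & np.isfinite(mean) & np.isfinite(sd) & (np.abs(mean) > 0)
    if usable.any():
        n[usable] = per_arm_sample_size(np.abs(mean[usable]), sd[usable], p)
        status = "ok"
    else:
        status = "warning: empty mask, no voxels to power"
    return PowerMap(
        mean_change=mean,
        sd_change=sd,
        p_value=stats_dict["p"],
        fdr_mask=mask,
        n_per_arm=n,
        params=p,
        status=status,
    )


def roi_summary_from_map(power_map: PowerMap, labels, roi_ids) -> pd.DataFrame:
    """Per-ROI minimum and median per-arm n over masked voxels."""
    rows = []
    for roi, lab in roi_ids.items():
        vals = power_map.n_per_arm[labels == lab]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "roi": roi,
                "n_masked_voxels": int(vals.size),
                "n_min": float(np.min(vals)) if vals.size else math.nan,
                "n_median": float(np.median(vals)) if vals.size else math.nan,
            }
        )
    return pd.DataFrame(rows)


def roi_power_table(
    change_table: pd.DataFrame,
    groups: pd.Series | dict,
    params: PowerParams | None = None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-ROI, per-group Δμ, σ and per-arm sample size.

    ``change_table`` is the long table from ``roi_change_table`` (columns
    subject_id, roi, q_value; the averaged-cluster rows are treated as one
    more ROI). ``groups`` maps subject_id to a group label.
    """
    p = params or PowerParams()
    p.validate()
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    tab = change_table.copy()
    tab["group"] = tab["subject_id"].map(groups)
    tab = tab.dropna(subset=["group"])
    rows = []
    for (roi, grp), sub in tab.groupby(["roi", "group"], sort=True):
        n_subj = len(sub)
        if n_subj < min_group:
            raise ValueError(
                f"group {grp!r} has {n_subj} subjects in ROI {roi!r}; need {min_group}"
            )
        delta_mu = abs(float(sub["q_value"].mean()))
        sigma = float(sub["q_value"].std(ddof=1))
        n_arm = (
            per_arm_sample_size(delta_mu, sigma, p) if delta_mu > 0 else np.nan
        )
        rows.append(
            {
                "roi": roi,
                "group": grp,
                "n_subjects": n_subj,
                "delta_mu": delta_mu,
                "sigma": sigma,
                "n_per_arm": n_arm,
            }
        )
    return pd.DataFrame(rows)
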