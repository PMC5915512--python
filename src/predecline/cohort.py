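"""Seeded synthetic cohorts with stratified biomarker structure and
sigmoid-driven metabolic decline.

The generator emulates a cognitively normal elderly cohort in which
2-year FDG-PET metabolic decline depends sigmoidally on baseline amyloid
burden (florbetapir SUVR) and CSF phosphorylated tau (p-tau, pg/ml).
Subjects are drawn from strata defined by the standard abnormality
thresholds (SUVR > 1.15, p-tau > 23) and the proposed imminent-decline
thresholds (SUVR > 1.228, p-tau > 45), so group classification is exact
by construction. Expected annualized percent change in each region of
interest (ROI) follows

    Q(r) = drift - M_r * L((B_A - c_A)/d_A) * L((B_T - c_T)/d_T)

with ``L`` the standard logistic, ``B_A``/``B_T`` the subject's amyloid
and tau biomarkers, ``c``/``d`` inflections and steepnesses, and ``M_r``
the maximal AD-related decline of the ROI (0 for control ROIs). Gaussian
residual noise of SD ``sigma_q`` is added to the change statistic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .groups import ThresholdSet

__all__ = [
    "StratumSpec",
    "DeclineModel",
    "CohortConfig",
    "ImageConfig",
    "VolumePair",
    "ROI_MAX_DECLINE",
    "AD_SIGNATURE_ROIS",
    "CONTROL_ROIS",
    "default_strata",
    "generate_cohort",
    "generate_volume_pairs",
    "write_cohort",
    "read_cohort",
]

#: Maximal AD-related annualized decline (% per year) per ROI.
ROI_MAX_DECLINE: dict[str, float] = {
    "mediobasal_temporal": 3.4,
    "orbitofrontal": 3.0,
    "anterior_cingulate": 2.8,
    "posterior_cingulate": 2.8,
    "lateral_temporal": 2.5,
    "precuneus": 0.0,
    "occipital": 0.0,
}

#: ROIs forming the AD-signature averaged cluster.
AD_SIGNATURE_ROIS: tuple[str, ...] = (
    "mediobasal_temporal",
    "orbitofrontal",
    "anterior_cingulate",
    "posterior_cingulate",
)

#: ROIs with no AD-related decline, used as negative controls.
CONTROL_ROIS: tuple[str, ...] = ("precuneus", "occipital")

# Rejection-sampling margins kept clear of classification boundaries so
# that stratum membership is never decided by floating-point ties.
MARGIN_SUVR = 0.005
MARGIN_PTAU = 0.5


@dataclass(frozen=True)
class StratumSpec:
    """One biomarker stratum: admissible region, target moments, demographics."""

    label: str
    count: int
    suvr_bounds: tuple[float, float]
    ptau_bounds: tuple[float, float]
    suvr_mean: float
    suvr_sd: float
    ptau_mean: float
    ptau_sd: float
    apoe4_prob: float
    age_mean: float = 74.5
    age_sd: float = 6.5
    male_prob: float = 0.5
    education_mean: float = 16.5
    education_sd: float = 2.7
    mmse_mean: float = 29.0
    mmse_sd: float = 1.1

    def validate(self) -> None:
        if self.count < 0:
            raise ValueError(f"stratum {self.label!r}: count must be >= 0")
        if self.suvr_sd <= 0 or self.ptau_sd <= 0:
            raise ValueError(f"stratum {self.label!r}: sd values must be > 0")
        for name, (lo, hi) in (
            ("suvr_bounds", self.suvr_bounds),
            ("ptau_bounds", self.ptau_bounds),
        ):
            if not lo < hi:
                raise ValueError(f"stratum {self.label!r}: {name} must be ordered")
        if not 0.0 <= self.apoe4_prob <= 1.0:
            raise ValueError(f"stratum {self.label!r}: apoe4_prob outside [0, 1]")


@dataclass(frozen=True)
class DeclineModel:
    """Generative sigmoid dependence of metabolic decline on both biomarkers.

    Inflections default to the imminent-decline thresholds; ``roi_max_decline``
    maps each ROI to its maximal AD-related decline M_r (% per year, 0 for
    control regions); ``drift`` is the aging drift common to all ROIs and
    ``sigma_q`` the residual SD of the per-ROI change statistic.
    """

    c_amyloid: float = 1.228
    d_amyloid: float = 0.02
    c_tau: float = 45.0
    d_tau: float = 3.0
    roi_max_decline: dict[str, float] = field(
        default_factory=lambda: dict(ROI_MAX_DECLINE)
    )
    drift: float = -0.1
    sigma_q: float = 2.0

    def expected_change(
        self, roi: str, suvr: np.ndarray | float, ptau: np.ndarray | float
    ) -> np.ndarray | float:
        """Expected annualized percent change Q(r) for the given biomarkers."""
        from scipy.special import expit

        m = self.roi_max_decline[roi]
        gate = expit((np.asarray(suvr) - self.c_amyloid) / self.d_amyloid) * expit(
            (np.asarray(ptau) - self.c_tau) / self.d_tau
        )
        return self.drift - m * gate


def default_strata() -> list[StratumSpec]:
    """The default 120-subject stratification.

    Counts 24 / (3 + 60) / 16 / 17 reproduce the biomarker-negative,
    at-risk, preclinical-below and preclinical-above group sizes, with the
    at-risk stratum split 3 amyloid-only / 60 tau-only so that exactly
    36/120 = 30% of subjects are amyloid-positive at SUVR > 1.15.
    """
    return [
        StratumSpec(
            label="biomarker_negative",
            count=24,
            suvr_bounds=(0.70, 1.15),
            ptau_bounds=(5.0, 23.0),
            suvr_mean=1.00,
            suvr_sd=0.03,
            ptau_mean=19.3,
            ptau_sd=2.9,
            apoe4_prob=0.04,
            age_mean=75.1,
            age_sd=7.4,
            male_prob=0.58,
            education_mean=17.7,
            education_sd=2.5,
            mmse_mean=29.1,
            mmse_sd=1.4,
        ),
        StratumSpec(
            label="amyloid_only",
            count=3,
            suvr_bounds=(1.15, 1.60),
            ptau_bounds=(5.0, 23.0),
            suvr_mean=1.22,
            suvr_sd=0.06,
            ptau_mean=19.5,
            ptau_sd=2.9,
            apoe4_prob=0.27,
            age_mean=73.9,
            age_sd=6.1,
            male_prob=0.55,
            education_mean=16.3,
            education_sd=2.9,
            mmse_mean=29.2,
            mmse_sd=0.96,
        ),
        StratumSpec(
            label="tau_only",
            count=60,
            suvr_bounds=(0.70, 1.15),
            ptau_bounds=(23.0, 120.0),
            suvr_mean=1.05,
            suvr_sd=0.05,
            ptau_mean=36.0,
            ptau_sd=12.0,
            apoe4_prob=0.27,
            age_mean=73.9,
            age_sd=6.1,
            male_prob=0.55,
            education_mean=16.3,
            education_sd=2.9,
            mmse_mean=29.2,
            mmse_sd=0.96,
        ),
        StratumSpec(
            label="preclinical_below",
            count=16,
            suvr_bounds=(1.15, 1.60),
            ptau_bounds=(23.0, 45.0),
            suvr_mean=1.25,
            suvr_sd=0.08,
            ptau_mean=36.5,
            ptau_sd=8.9,
            apoe4_prob=0.38,
            age_mean=74.9,
            age_sd=6.2,
            male_prob=0.44,
            education_mean=15.6,
            education_sd=2.4,
            mmse_mean=28.9,
            mmse_sd=0.97,
        ),
        StratumSpec(
            label="preclinical_above",
            count=17,
            suvr_bounds=(1.228, 1.60),
            ptau_bounds=(45.0, 130.0),
            suvr_mean=1.35,
            suvr_sd=0.07,
            ptau_mean=56.4,
            ptau_sd=15.8,
            apoe4_prob=0.35,
            age_mean=78.6,
            age_sd=5.1,
            male_prob=0.42,
            education_mean=16.7,
            education_sd=2.5,
            mmse_mean=29.0,
            mmse_sd=0.92,
        ),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of a synthetic cohort draw."""

    seed: int = 0
    strata: list[StratumSpec] = field(default_factory=default_strata)
    decline: DeclineModel = field(default_factory=DeclineModel)
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    followup_months_mean: float = 24.0
    followup_months_sd: float = 1.0
    followup_months_bounds: tuple[float, float] = (18.0, 30.0)
    baseline_suvr_mean: float = 1.30
    baseline_suvr_sd: float = 0.10
    # CSF Abeta as a monotone-decreasing noisy transform of amyloid SUVR,
    # calibrated so |Spearman rho| with SUVR is about 0.68 in large samples.
    abeta_intercept: float = 420.0
    abeta_slope: float = -220.0
    abeta_noise_sd: float = 31.0
    abeta_floor: float = 40.0

    @property
    def n(self) -> int:
        return sum(s.count for s in self.strata)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _truncnorm(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Vectorized rejection sampling from a truncated normal."""
    if not lo < hi:
        raise ValueError("empty truncation interval")
    out = np.empty(0)
    tries = 0
    while out.size < n:
        draw = rng.normal(mean, sd, size=max(4 * n, 64))
        out = np.concatenate([out, draw[(draw > lo) & (draw < hi)]])
        tries += 1
        if tries > 1000:
            raise RuntimeError(
                f"truncated-normal rejection sampling failed for "
                f"N({mean}, {sd}) on ({lo}, {hi})"
            )
    return out[:n]


def _effective_bounds(
    bounds: tuple[float, float], thresholds: tuple[float, ...], margin: float
) -> tuple[float, float]:
    """Shrink bounds that coincide with a classification threshold by `margin`."""
    lo, hi = bounds
    for t in thresholds:
        if np.isclose(lo, t):
            lo = t + margin
        if np.isclose(hi, t):
            hi = t - margin
    if not lo < hi:
        raise ValueError(f"bounds {bounds} collapse after margin {margin}")
    return lo, hi


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Draw a seeded synthetic cohort as one DataFrame row per subject.

    Columns: subject_id, stratum, age, sex, education, mmse, apoe4,
    florbetapir_suvr, csf_ptau, csf_abeta, followup_months, and a
    ``{roi}_baseline`` / ``{roi}_followup`` pair per ROI. The full
    configuration is attached as ``df.attrs["config"]``.

    Deterministic given ``config.seed``: the same configuration yields an
    identical table.
    """
    if config is None:
        config = CohortConfig()
    for s in config.strata:
        s.validate()
    thr = config.thresholds
    thr.validate()
    rng = np.random.default_rng(config.seed)
    rois = list(config.decline.roi_max_decline)

    frames = []
    offset = 0
    suvr_thresholds = (thr.suvr_standard, thr.suvr_proposed)
    ptau_thresholds = (thr.ptau_standard, thr.ptau_proposed)
    for s in config.strata:
        n = s.count
        suvr_lo, suvr_hi = _effective_bounds(s.suvr_bounds, suvr_thresholds, MARGIN_SUVR)
        ptau_lo, ptau_hi = _effective_bounds(s.ptau_bounds, ptau_thresholds, MARGIN_PTAU)
        suvr = _truncnorm(rng, n, s.suvr_mean, s.suvr_sd, suvr_lo, suvr_hi)
        ptau = _truncnorm(rng, n, s.ptau_mean, s.ptau_sd, ptau_lo, ptau_hi)
        age = _truncnorm(rng, n, s.age_mean, s.age_sd, 55.0, 95.0)
        sex = np.where(rng.random(n) < s.male_prob, "M", "F")
        education = _truncnorm(rng, n, s.education_mean, s.education_sd, 6.0, 24.0)
        mmse = np.clip(np.round(rng.normal(s.mmse_mean, s.mmse_sd, n)), 24, 30)
        apoe4 = rng.random(n) < s.apoe4_prob
        followup = _truncnorm(
            rng,
            n,
            config.followup_months_mean,
            config.followup_months_sd,
            *config.followup_months_bounds,
        )
        abeta = np.maximum(
            config.abeta_intercept
            + config.abeta_slope * suvr
            + rng.normal(0.0, config.abeta_noise_sd, n),
            config.abeta_floor,
        )
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{offset + i:04d}" for i in range(n)],
                "stratum": s.label,
                "age": age,
                "sex": sex,
                "education": education,
                "mmse": mmse,
                "apoe4": apoe4,
                "florbetapir_suvr": suvr,
                "csf_ptau": ptau,
                "csf_abeta": abeta,
                "followup_months": followup,
            }
        )
        dt_years = followup / 12.0
        for roi in rois:
            base = _truncnorm(
                rng, n, config.baseline_suvr_mean, config.baseline_suvr_sd, 0.5, np.inf
            )
            q = config.decline.expected_change(roi, suvr, ptau) + rng.normal(
                0.0, config.decline.sigma_q, n
            )
            frame[f"{roi}_baseline"] = base
            # multiplicative injection: the annualized change statistic
            # recovers q exactly by construction
            frame[f"{roi}_followup"] = base * (1.0 + q * dt_years / 100.0)
        frames.append(frame)
        offset += n

    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        cols = [
            "subject_id",
            "stratum",
            "age",
            "sex",
            "education",
            "mmse",
            "apoe4",
            "florbetapir_suvr",
            "csf_ptau",
            "csf_abeta",
            "followup_months",
        ]
        for roi in rois:
            cols += [f"{roi}_baseline", f"{roi}_followup"]
        df = pd.DataFrame(columns=cols)
    df.attrs["config"] = config
    df.attrs["rois"] = rois
    return df


# ---------------------------------------------------------------------------
# Paired 3-D volumes (stand-ins for preprocessed PET maps)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageConfig:
    """Geometry and noise of the synthetic paired volumes."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 4.0
    noise_sd: float = 0.05
    background_value: float = 0.9


@dataclass
class VolumePair:
    """Paired baseline/follow-up volumes with an integer ROI label volume."""

    subject_id: str
    baseline: np.ndarray
    followup: np.ndarray
    labels: np.ndarray
    voxel_size: float
    roi_ids: dict[str, int]


def default_label_volume(
    rois: list[str], shape: tuple[int, int, int] = (32, 32, 32)
) -> tuple[np.ndarray, dict[str, int]]:
    """Disjoint box masks, one per ROI, inside a zero (background) grid."""
    labels = np.zeros(shape, dtype=np.int16)
    roi_ids = {}
    box = max(2, min(shape) // 4)
    for i, roi in enumerate(rois):
        x0 = 2 + (shape[0] // 2) * (i % 2)
        y0 = 2 + (shape[1] // 2) * ((i // 2) % 2)
        z0 = 2 + (shape[2] // 2) * (i // 4)
        if z0 + box > shape[2]:
            raise ValueError(f"cannot place {len(rois)} ROI boxes in grid {shape}")
        labels[x0 : x0 + box, y0 : y0 + box, z0 : z0 + box] = i + 1
        roi_ids[roi] = i + 1
    return labels, roi_ids


def generate_volume_pairs(
    cohort: pd.DataFrame,
    image_config: ImageConfig | None = None,
    labels: np.ndarray | None = None,
    roi_ids: dict[str, int] | None = None,
    seed: int = 0,
) -> list[VolumePair]:
    """Render each subject's ROI panel into paired noisy 3-D volumes.

    Every voxel of an ROI box carries the subject's panel value for that
    ROI plus i.i.d. Gaussian voxel noise, so the ROI mean of the volume
    estimates the panel value with SE ``noise_sd / sqrt(n_voxels)``.
    """
    cfg = image_config or ImageConfig()
    rois = list(cohort.attrs.get("rois", ROI_MAX_DECLINE))
    if labels is None:
        labels, roi_ids = default_label_volume(rois, cfg.shape)
    if roi_ids is None:
        raise ValueError("roi_ids must accompany a custom label volume")
    if labels.shape != cfg.shape:
        raise ValueError(
            f"label volume shape {labels.shape} != image shape {cfg.shape}"
        )
    for roi, lab in roi_ids.items():
        if not np.any(labels == lab):
            raise ValueError(f"ROI {roi!r} (label {lab}) has an empty mask")
    rng = np.random.default_rng(seed)
    pairs = []
    for _, row in cohort.iterrows():
        base = np.full(cfg.shape, cfg.background_value)
        follow = np.full(cfg.shape, cfg.background_value)
        for roi, lab in roi_ids.items():
            mask = labels == lab
            base[mask] = row[f"{roi}_baseline"]
            follow[mask] = row[f"{roi}_followup"]
        if cfg.noise_sd > 0:
            base = base + rng.normal(0.0, cfg.noise_sd, cfg.shape)
            follow = follow + rng.normal(0.0, cfg.noise_sd, cfg.shape)
        pairs.append(
            VolumePair(
                subject_id=row["subject_id"],
                baseline=base,
                followup=follow,
                labels=labels,
                voxel_size=cfg.voxel_size,
                roi_ids=dict(roi_ids),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, csv_path, sidecar_path=None) -> None:
    """Write the cohort CSV plus a JSON sidecar with configuration and seed."""
    cohort.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        config = cohort.attrs.get("config")
        payload = config.to_dict() if config is not None else {}
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def read_cohort(csv_path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(csv_path)
    df.attrs["rois"] = [
        c[: -len("_baseline")] for c in df.columns if c.endswith("_baseline")
    ]
    return df
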