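"""Supra-threshold response curves, four-parameter sigmoid fits, and
inflection-based threshold estimation.

For a biomarker B and per-subject annualized change Q, the supra-threshold
curve tabulates Y(t) = mean{ Q_i : B_i >= t } over the ascending candidate
thresholds t (the observed biomarker values). Y is then modelled as

    Y = a + b / (1 + exp(-(X - c) / d))

where ``a`` is the low-X asymptote, ``b`` the total change between
asymptotes (negative for decline), ``c`` the inflection location in
biomarker units, and ``d > 0`` the steepness. The fitted ``c`` is reported
as the biomarker threshold predictive of imminent metabolic decline. A
straight line is fitted to the same curve and the two models are compared
by AICc; the Akaike weight of the preferred model is its probability of
correctness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NonIdentifiedError",
    "ThresholdCurve",
    "SigmoidFit",
    "LinearFit",
    "ModelComparison",
    "ThresholdEstimate",
    "build_threshold_curve",
    "evaluate_sigmoid",
    "fit_sigmoid",
    "fit_linear",
    "compare_models_aicc",
    "estimate_threshold",
    "threshold_analysis",
]


class NonIdentifiedError(ValueError):
    """Raised when the curve carries no information about the sigmoid."""


@dataclass
class ThresholdCurve:
    """Supra-threshold mean-change curve for one biomarker."""

    biomarker: str
    thresholds: np.ndarray
    mean_response: np.ndarray
    tail_count: np.ndarray

    def __len__(self) -> int:
        return len(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "mean_response": self.mean_response,
                "tail_count": self.tail_count,
            }
        )


def build_threshold_curve(
    biomarker_values,
    change_values,
    min_tail: int = 5,
    biomarker: str = "biomarker",
) -> ThresholdCurve:
    """Tabulate supra-threshold mean change at each observed biomarker value.

    Candidates are the sorted distinct observed values; the response at a
    candidate t is the mean change over subjects with biomarker >= t.
    Candidates whose tail holds fewer than ``min_tail`` subjects are
    dropped (they produce unstable means at the far right of the curve).
    """
    b = np.asarray(biomarker_values, dtype=float)
    q = np.asarray(change_values, dtype=float)
    if b.shape != q.shape or b.ndim != 1:
        raise ValueError("biomarker and change arrays must be 1-D and aligned")
    if b.size < min_tail:
        raise ValueError(f"need at least min_tail={min_tail} subjects, got {b.size}")
    order = np.argsort(b, kind="stable")
    b_sorted = b[order]
    q_sorted = q[order]
    # suffix sums: tail at threshold b_sorted[i] starts at the first
    # occurrence of that value
    suffix_sum = np.cumsum(q_sorted[::-1])[::-1]
    n = b.size
    candidates, first_idx = np.unique(b_sorted, return_index=True)
    tail_count = n - first_idx
    mean_response = suffix_sum[first_idx] / tail_count
    keep = tail_count >= min_tail
    return ThresholdCurve(
        biomarker=biomarker,
        thresholds=candidates[keep],
        mean_response=mean_response[keep],
        tail_count=tail_count[keep].astype(int),
    )


def evaluate_sigmoid(params, x):
    """Four-parameter sigmoid a + b / (1 + exp(-(x - c)/d)); requires d > 0."""
    a, b, c, d = params
    if d <= 0:
        raise ValueError("steepness d must be > 0")
    x = np.asarray(x, dtype=float)
    out = a + b * _logistic((x - c) / d)
    return out.item() if out.ndim == 0 else out


def _logistic(z):
    from scipy.special import expit

    return expit(np.asarray(z, dtype=float))


def _aicc(rss: float, n: int, k: int, corrected: bool = True) -> float:
    """Gaussian-likelihood AIC(c): n ln(RSS/n) + 2k (+ small-sample term).

    ``k`` counts the fitted parameters plus one for the residual variance.
    """
    rss = max(float(rss), np.finfo(float).tiny)
    aic = n * math.log(rss / n) + 2 * k
    if corrected:
        if n - k - 1 <= 0:
            return math.inf
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float
    d: float
    rss: float
    r_squared: float
    f_stat: float
    f_p: float
    aicc: float
    converged: bool
    c_se: float
    c_ci95: tuple[float, float]
    n: int
    x_range: tuple[float, float]
    message: str = ""

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class LinearFit:
    slope: float
    intercept: float
    rss: float
    r_squared: float
    aicc: float
    n: int


@dataclass
class ModelComparison:
    preferred: str
    delta_aicc: float
    prob_correct: float
    prob_linear: float
    prob_sigmoid: float


@dataclass
class ThresholdEstimate:
    c: float
    ci95: tuple[float, float]
    extrapolated: bool


def _sigmoid_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Multi-start grid: c at X quartiles, d at fractions of the X range
    (including a near-linear, very shallow configuration)."""
    xr = float(np.ptp(x))
    a0 = float(np.min(y))
    trend = np.polyfit(x, y, 1)[0]
    b0 = float(np.ptp(y)) * (1.0 if trend >= 0 else -1.0)
    starts = []
    for cq in np.quantile(x, [0.25, 0.5, 0.75]):
        for d0 in (xr / 10.0, xr / 30.0, 2.0 * xr):
            starts.append(np.array([a0, b0, cq, d0]))
    return starts


def fit_sigmoid(curve: ThresholdCurve, use_aicc: bool = True) -> SigmoidFit:
    """Least-squares sigmoid fit with multi-start local optimization.

    Starts combine a = min Y, b = Y-range signed by the linear trend,
    c at the X quartiles and d at X-range/10, /30 and 2x the X range (the
    last approximating a straight line, so the sigmoid never fits worse
    than the linear model). The best-RSS converged solution is returned
    with an asymptotic (Jacobian-based) standard error and 95% CI for c.
    """
    x = np.asarray(curve.thresholds, dtype=float)
    y = np.asarray(curve.mean_response, dtype=float)
    n = x.size
    if n < 6:
        raise ValueError(f"need at least 6 curve points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate X range")
    if np.ptp(y) == 0:
        raise NonIdentifiedError("constant response curve: sigmoid not identified")

    def residuals(p):
        a, b, c, d = p
        return a + b * _logistic((x - c) / d) - y

    def jacobian(p):
        a, b, c, d = p
        s = _logistic((x - c) / d)
        ds = s * (1.0 - s)
        return np.column_stack(
            [np.ones_like(x), s, -b * ds / d, -b * ds * (x - c) / d**2]
        )

    xr = float(np.ptp(x))
    lower = np.array([-np.inf, -np.inf, -np.inf, 1e-9 * xr])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])
    best = None
    best_fallback = None
    messages = []
    for p0 in _sigmoid_starts(x, y):
        p0 = np.clip(p0, lower + 1e-12, None)
        try:
            res = optimize.least_squares(
                residuals,
                p0,
                jac=jacobian,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - optimizer failure path
            messages.append(str(exc))
            continue
        if not res.success:
            # budget exhausted along a flat valley: keep as fallback —
            # the parameters are still a usable local solution
            messages.append(res.message)
            if best_fallback is None or res.cost < best_fallback.cost:
                best_fallback = res
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None and best_fallback is not None and np.all(
        np.isfinite(best_fallback.x)
    ):
        best = best_fallback
    if best is None:
        return SigmoidFit(
            a=math.nan, b=math.nan, c=math.nan, d=math.nan,
            rss=math.nan, r_squared=math.nan, f_stat=math.nan, f_p=math.nan,
            aicc=math.nan, converged=False, c_se=math.nan,
            c_ci95=(math.nan, math.nan), n=n,
            x_range=(float(x.min()), float(x.max())),
            message="; ".join(messages) or "no start converged",
        )

    a, b, c, d = best.x
    rss = float(2.0 * best.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    p_model = 4
    dof = n - p_model
    # F-test of the regression against the constant-mean model
    if dof > 0 and rss > 0:
        f_stat = ((tss - rss) / (p_model - 1)) / (rss / dof)
        f_p = float(stats.f.sf(f_stat, p_model - 1, dof))
    else:
        f_stat, f_p = math.inf, 0.0
    # asymptotic covariance of the parameters from the Jacobian
    s2 = rss / dof if dof > 0 else 0.0
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * s2
    c_se = float(np.sqrt(max(cov[2, 2], 0.0)))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else math.inf
    half = tcrit * c_se
    return SigmoidFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        rss=rss, r_squared=r2, f_stat=float(f_stat), f_p=f_p,
        aicc=_aicc(rss, n, k=p_model + 1, corrected=use_aicc),
        converged=True, c_se=c_se, c_ci95=(float(c - half), float(c + half)),
        n=n, x_range=(float(x.min()), float(x.max())),
    )


def fit_linear(curve: ThresholdCurve, use_aicc: bool = True) -> LinearFit:
    """Ordinary least squares on the (threshold, response) curve."""
    x = np.asarray(curve.thresholds, dtype=float)
    y = np.asarray(curve.mean_response, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 curve points, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate X range")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        rss=rss,
        r_squared=r2,
        aicc=_aicc(rss, n, k=3, corrected=use_aicc),
        n=n,
    )


def compare_models_aicc(linear: LinearFit, sigmoid: SigmoidFit) -> ModelComparison:
    """Akaike-weight comparison of the linear and sigmoid fits.

    The preferred (lower-AICc) model has probability of correctness
    w = 1 / (1 + exp(-delta/2)) with delta the absolute AICc difference;
    the two probabilities sum to 1.
    """
    if linear.n != sigmoid.n:
        raise ValueError(
            f"fits computed on different data: n={linear.n} vs n={sigmoid.n}"
        )
    delta = sigmoid.aicc - linear.aicc
    # Akaike weights of the two candidates
    w_sig = 1.0 / (1.0 + math.exp(min(delta / 2.0, 700.0))) if delta < 1400 else 0.0
    w_lin = 1.0 - w_sig
    if delta < 0:
        preferred, prob = "sigmoid", w_sig
    else:
        preferred, prob = "linear", w_lin
    return ModelComparison(
        preferred=preferred,
        delta_aicc=abs(float(delta)),
        prob_correct=float(prob),
        prob_linear=float(w_lin),
        prob_sigmoid=float(w_sig),
    )


def estimate_threshold(fit: SigmoidFit) -> ThresholdEstimate:
    """Read the inflection location c as the imminent-decline threshold."""
    if not fit.converged:
        raise ValueError("cannot estimate a threshold from a non-converged fit")
    lo, hi = fit.x_range
    return ThresholdEstimate(
        c=fit.c,
        ci95=fit.c_ci95,
        extrapolated=not (lo <= fit.c <= hi),
    )


def threshold_analysis(
    biomarker_values,
    change_values,
    min_tail: int = 5,
    biomarker: str = "biomarker",
) -> dict:
    """Curve -> linear and sigmoid fits -> AICc comparison -> threshold.

    Convenience wrapper returning all intermediate objects in a dict.
    """
    curve = build_threshold_curve(
        biomarker_values, change_values, min_tail=min_tail, biomarker=biomarker
    )
    sig = fit_sigmoid(curve)
    lin = fit_linear(curve)
    comparison = compare_models_aicc(lin, sig)
    estimate = estimate_threshold(sig) if sig.converged else None
    return {
        "curve": curve,
        "sigmoid": sig,
        "linear": lin,
        "comparison": comparison,
        "estimate": estimate,
    }
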