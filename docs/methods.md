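# Methods

## The analysis in brief

`predecline` implements a threshold-analysis framework for preclinical
Alzheimer's disease: given cognitively normal subjects with a baseline
amyloid-PET florbetapir SUVR, a baseline CSF p-tau concentration, and
longitudinal FDG-PET, it asks at which biomarker levels metabolic decline
becomes imminent, and how much biomarker-based enrichment shrinks the
sample size of a hypothetical disease-modifying trial that uses FDG
change as its surrogate outcome.

The change statistic is the annualized percent change

    Q = ((SUVR_followup − SUVR_baseline) / SUVR_baseline) · 100 / Δt,

with Δt in years. Follow-up intervals are stored in months and divided by
12; an alternative convention (total 2-year change) would scale every Q,
σ and Δμ by the same factor and leave all sample-size ratios unchanged.

### Supra-threshold curves and sigmoid fits

For a biomarker B, the curve Y(t) is the mean Q among subjects with
B ≥ t, tabulated at every distinct observed value of B (candidates whose
tail holds fewer than `min_tail = 5` subjects are dropped; the tail means
of 1–4 subjects are too unstable to constrain the fit). Y is modelled as
a four-parameter logistic

    Y = a + b / (1 + exp(−(X − c)/d)),

where `a` is the low-X asymptote, `b` the (typically negative) total
change between asymptotes, `c` the inflection location in biomarker
units — reported as the imminent-decline threshold — and `d > 0` the
steepness. Fitting is multi-start bounded least squares (trust-region
reflective): `a` starts at min Y, `b` at the Y-range signed by the linear
trend, `c` at the X quartiles, and `d` at X-range/10, X-range/30 and 2 ×
X-range. The last, nearly linear, start guarantees the sigmoid never ends
worse than the straight line, so sigmoid RSS ≤ linear RSS always holds.
A start that exhausts its iteration budget on a flat valley is kept as a
fallback solution; the best-RSS solution wins.

The straight line is fitted by OLS to the same curve and the two models
are compared by AICc (`n ln(RSS/n) + 2k + 2k(k+1)/(n−k−1)`, `k` = fitted
parameters + 1 for the residual variance: 5 for the sigmoid, 3 for the
line; plain AIC available via `use_aicc=False`). The preferred model's
probability of correctness is its Akaike weight
`1/(1 + exp(−|ΔAICc|/2))`.

The CI for `c` is asymptotic: the parameter covariance is
`s² (JᵀJ)⁻¹` from the Jacobian at the solution, with a Student-t
quantile at n − 4 degrees of freedom. With noiseless input the CI width
collapses to zero. An estimate outside the observed X range is flagged as
extrapolated rather than rejected: a runaway `c` is a legitimate (if
useless) least-squares answer on curves that are not sigmoid-shaped.

### Threshold grid

Candidates per axis are the subjects' observed values with ties kept, so
n subjects give exactly n × n cells (120 → 14,400). Per cell the group
is every subject with both biomarkers at or above the pair; the mean Q is
reported for groups of at least `min_cell = 3` (smaller cells are
missing, never zero), and a two-sided one-sample t-test of the mean
against zero is attached for groups of ≥ 3 with positive variance.
Categories: both at/below standard; exactly one above standard; both
above standard with at least one below proposed; both **at or above** the
proposed pair (the red, enriched region uses ≥, the standard comparisons
use strict >).

### Classification

Strict `>` at every threshold (standard 1.15 SUVR / 23 pg/ml; proposed
1.228 SUVR / 45 pg/ml). Biomarker-negative = neither abnormal; at-risk =
exactly one; preclinical = both; `above_proposed` additionally requires
both biomarkers strictly above the proposed pair. The synthetic
generator's sampling margins (0.005 SUVR, 0.5 pg/ml) keep every subject
away from the boundaries, so the strictness convention never decides a
classification on synthetic data.

### Power analysis

Per-arm sample size for a two-arm trial detecting a fractional effect β
on the mean change:

    n = (∂ + δ)² · 2σ² / (Δμ · β)²,

with the printed coefficients ∂ = 0.842 (80% power) and δ = 1.96 (5%
two-sided significance) used verbatim rather than re-derived normal
quantiles, so the worked arithmetic reproduces bit for bit; Δμ enters as
an absolute value; results are rounded up to the next whole subject and
floored at 1. The empirical contract — a two-sample t-test at the
computed n rejects in ≈80% of simulated trials — is validated by
simulation in the test suite (78–84% over 10,000 replicates).

Voxel-wise, a one-sample two-sided t-test of mean change against zero is
run per voxel (voxels missing in any subject, or with zero variance, are
propagated as missing), significance is controlled with Benjamini–
Hochberg FDR at q = 0.001 (statsmodels `fdr_bh`; "FDR at P < 0.001" is
read as BH-adjusted p < 0.001, which coincides with BH rejection at
q = 0.001), and the formula is evaluated at masked voxels only.

### Group contrasts

Per ROI, OLS of Q on group plus covariates (age, sex, education, APOE-ε4
by default; education can be dropped to match the narrower adjustment
set), with pairwise group differences read off as contrasts of the group
coefficients. Bonferroni multiplicity defaults to (ROIs) × (group pairs)
and is declared in every result. Chi-squared tests for categorical
demographics omit the continuity correction because the tables are
generally larger than 2 × 2.

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, since
the source data sit behind a controlled-access agreement. It is a
first-class, tested component, not a fixture.

**Strata.** 120 subjects: 24 biomarker-negative, 63 at-risk (split 3
amyloid-only / 60 tau-only so that exactly 36/120 = 30% of subjects are
amyloid-positive at SUVR > 1.15, matching the reported positivity rate;
the published table does not report the split), 16 preclinical below the
proposed thresholds, 17 above. Biomarkers are drawn by truncated-normal
rejection sampling inside each stratum's admissible region, with margins
of 0.005 SUVR / 0.5 pg/ml from every classification boundary so the
classifier recovers the generating stratum for 100% of subjects and the
headline counts (24/63/33 with 17 above-proposed) are exact for every
seed. Stratum moments (biomarkers, age, sex, education, MMSE, APOE-ε4)
follow the published group table.

**Decline model.** Expected annualized change per ROI r:

    Q̄_r = drift − M_r · L((B_A − c_A)/d_A) · L((B_T − c_T)/d_T),

with L the standard logistic, inflections c_A = 1.228 SUVR and c_T = 45
pg/ml, steepnesses d_A = 0.02 and d_T = 3.0, an aging drift of −0.1 %/yr
common to all ROIs, and maximal AD declines M_r of 3.4 (mediobasal
temporal), 3.0 (orbitofrontal), 2.8 (anterior and posterior cingulate),
2.5 (lateral temporal) and 0 (precuneus, occipital — the control
regions) % per year. Gaussian residual noise with σ_Q = 2.0 %/yr is
added to the change statistic; decline is injected multiplicatively on
the baseline ROI SUVR so the annualized statistic recovers Q̄_r + noise
exactly. Follow-up ~ Normal(24, 1) months truncated to [18, 30]. CSF Aβ
is a monotone-decreasing noisy transform of SUVR calibrated to
|Spearman ρ| ≈ 0.68 in large samples; the association's sign is
negative, as biology dictates (higher brain amyloid, lower CSF Aβ).

**Volumes.** Optional paired 3-D volumes (default 32³ voxels) render each
subject's ROI panel into disjoint box masks plus i.i.d. voxel noise and a
uniform background labelled 0, standing in for preprocessed PET maps.
They share no features with real images beyond ROI-mean structure: no
smoothing, registration error, partial-volume effect or anatomy.

**What passing tests do and do not show.** The generator proves the
pipeline's correctness (exact counts, formula arithmetic, grid
cardinality, FDR behaviour, power contract) and its qualitative claims
(enrichment ordering of sample sizes, progressive decline in the red
grid region, null control ROIs). It does not certify behaviour on real
cohorts, where decline is not exactly logistic in the biomarkers,
biomarkers are not cleanly stratified, and measurement error is not
Gaussian or homoscedastic.

### A known structural limitation

The supra-threshold sweep on this generator does **not** return the
generative inflections. Y(t) is a tail mean, so its shape is dominated by
tail composition: as t sweeps the 70% of subjects below 1.15 SUVR, the
decliner fraction in the tail grows hyperbolically (≈ const/N(t)), and
above 1.228 the below-proposed stratum (high amyloid, tau below 45)
dilutes the tail. The best-fitting logistic of the ideal (noiseless,
large-n) curve therefore sits near 1.15–1.17 SUVR and ≈ 47.6 pg/ml
rather than 1.228/45, and at n = 120 the amyloid fit often runs away to
an extrapolated inflection (flagged by `estimate_threshold`). This is a
property of composing a hard stratification with a tail-mean sweep, not
of the fitting code: fits to curves generated directly from the logistic
model recover c to machine precision. Recovering inflections through the
sweep would require decliners whose amyloid values span the transition
region — as real cohorts presumably provide.

## Numerical choices and degenerate inputs

- Tie-breaks: curve candidates are distinct observed values; grid
  candidates keep ties so cell counts equal n².
- Constant-Y curves raise a non-identification error; degenerate X
  ranges are rejected; non-converged fits return `converged=False` with
  optimizer diagnostics and refuse to yield a threshold estimate.
- Zero baseline voxels inside a mask are counted, flagged and set
  missing; background is NaN, never 0, since 0 is a legal change value.
- Zero-variance voxel groups get missing p-values; σ = 0 groups in the
  power table floor at n = 1.
- AICc uses RSS clipped at the smallest positive float to keep noiseless
  fits finite in log-likelihood form.
- Problem sizes in the test suite (cohorts of 120–25,000, 10,000-voxel
  null simulations, 10,000 trial replicates, 50–100 fit replicates) were
  chosen to give comfortable Monte-Carlo margins for every asserted
  band.

## Design choices made where the design was open

- Annualized (per-year) units for Q everywhere; Δμ/σ calibrations are in
  these units.
- Candidate thresholds = observed values (reproduces the n² grid count
  exactly; an even grid was evaluated and changes nothing structural).
- CI for c is asymptotic/Jacobian-based; a subject-level bootstrap can be
  layered on by refitting resampled cohorts, but is not built in.
- `min_tail = 5` and `min_cell = 3` stabilize tail means and cell tests.
- The report schema is a pydantic model (`predecline.pipeline.Report`);
  validation happens on every write.

## Limitations

- No image preprocessing of any kind (registration, smoothing,
  reference-region normalization, partial-volume correction) — inputs
  are assumed already reduced to SUVR panels or aligned volumes.
- No cognition or diagnosis-conversion modelling; no CSF-Aβ-based
  classification or decline modelling.
- No cluster-extent or random-field inference on the maps; FDR only.
- The power formula is the classical two-sample normal approximation; no
  longitudinal mixed-effects power model.
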