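# Methods

This note documents the models, estimators and design choices behind
`copsway`, in the order the pipeline runs them.

## Signals and preprocessing

A trial is a two-channel CoP trajectory (anteroposterior and mediolateral,
cm) sampled at `fs` Hz, nominally 6000 samples of 60 s at 100 Hz. Channels
are low-pass filtered with a second-order Butterworth design at 20 Hz
applied forward and backward (`scipy.signal.filtfilt`), giving an effective
fourth-order zero-phase response; edges are handled by reflective padding of
`3·(order+1)` samples. Instantaneous velocity is the first difference of
the filtered signal times `fs`, yielding N−1 samples; all velocity
statistics use this convention. Trials whose sample count disagrees with
`fs × duration` by more than one sample are rejected rather than truncated,
because partial recordings are not comparable with complete ones.

## Linear metrics

* `velo` — mean planar speed. `velo_ap`, `velo_ml` — means of the
  *rectified* per-axis velocity (the signed mean is ≈ 0 by construction and
  carries no information); `velo_sd_*` — sample SDs (n−1) of the *signed*
  velocity, so the SD is not a rescaled copy of the mean.
* `area` — 95% confidence-ellipse area `π·q₀.₉₅·√det(Σ̂)` with Σ̂ the 2×2
  sample covariance and `q₀.₉₅ = χ²₀.₉₅(2) ≈ 5.991`. Rank-deficient
  covariance returns 0 with a warning.
* `mfreq_*` — mean |velocity| divided by mean |position − trial mean|,
  per axis, in 1/s. This is the plain ratio definition; some conventions
  insert a 1/(2π) or similar constant, which users can apply downstream if
  they need cross-study comparability. The "spatial center" is the
  per-trial mean position — the only self-consistent reading.

## Nonlinear metrics

**Sway density (MP3, MT3, MD3).** `SDC(t)` is the time the trajectory
spends within 0.3 cm (the conventional 3 mm radius behind the "3" suffix)
of the position at sample `t`, computed with a k-d tree. The curve is
smoothed with a zero-phase second-order low-pass at 2.5 Hz before peak
picking; unsmoothed SDC peak counting is noise-dominated. Peaks must have
a prominence of at least 5% of the smoothed-curve range — zero-phase
filtering of plateau-like curves produces low-amplitude ringing that would
otherwise register as spurious peaks. MP3 is the mean peak value (s), MT3
the mean *inter-peak interval* (s), MD3 the mean planar distance between
CoP positions at successive peaks (cm). MT3 could alternatively be read as
mean peak duration; the inter-peak reading is pinned here and flagged, not
silently changeable. Fewer than two peaks leaves MT3/MD3 undefined (NaN).

**Katz fractal dimension.** `FD = log₁₀ n / (log₁₀ n + log₁₀(d/L))` with
`n` steps, `L` total planar path length, `d` maximal planar distance from
the first sample. Computed on the filtered trajectory, consistent with the
rest of the metric panel. A straight line gives exactly 1; `L = 0` returns
1 with a degeneracy warning.

**DFA.** The demeaned series is integrated; for each of ~20 log-spaced box
sizes from 10 to N/8 the profile is split into non-overlapping boxes taken
from both ends (so all samples are used), each detrended with an order-1
polynomial; α is the log–log slope of the RMS residual versus box size.
Order-1 detrending and this box range are the common defaults for
physiological series of this length.

**SDA.** The planar mean-square displacement `MSD(Δt)` is computed for lags
up to 10 s. Short- and long-term diffusion coefficients are the slopes of
least-squares lines over 0.1–0.8 s and 2–10 s respectively, divided by 4 to
express per-axis-equivalent coefficients (planar Brownian motion has
`MSD = 4DΔt`). The fits are done in linear coordinates; the critical point
(CriT, CriD) is the intersection of the two lines. Negative short-term
slopes, parallel fits, or intersections outside (0, 10 s] flag the result
with diagnostics instead of silently reporting a number.

**Multiscale entropy.** Sample entropy `−ln(A/B)` with template length
m = 2, Chebyshev distance, self-matches excluded; A and B count (m+1)- and
m-length matches over the N−m templates. The tolerance `r = 0.2·SD` is
computed once from the original (scale-1) series and held fixed across
scales — the canonical choice, which makes entropy decline across scales
for white noise as coarse-graining shrinks variance relative to the fixed
r. Scales 1, 10 and 40 are extracted per channel; at scale 40 a 6000-sample
trial leaves 150 coarse-grained points, where vanishing match counts are
possible and propagate as NaN, never as 0. The pairwise counting loop is
numba-compiled.

**Embedding selection.** The delay τ is the first minimum of the
histogram-based auto mutual information (32 bins, lags to 200). Two
numerical safeguards: (i) if the lag-1 MI already sits at the plugin
estimator's independence bias floor (≈ (B−1)²/2N nats) the series is
treated as memoryless and τ = 1; (ii) the raw MI curve jitters at the bin
resolution, so the minimum search runs on a 5-lag moving average and
requires the minimum to hold over a ±7-lag neighborhood; without this the
jitter triggers far-too-early minima on smooth periodic signals. If no
local minimum exists, the first lag with MI < I(1)/e is used, then the
global minimum. The dimension m is the smallest (≤ 10) whose
false-nearest-neighbor fraction drops below 1%, with distance-ratio
threshold 10 and attractor-size threshold 2; neighbor pairs whose
(m+1)-distance is at floating-point rounding level are exact repeats and
counted true (otherwise the distance ratio is pure rounding noise). The
false fraction is evaluated on an evenly strided subsample of ≤ 1500 query
points against the full tree.

**RQA.** Each channel is analyzed separately in its own embedding —
determinism and laminarity are reported per direction. Recurrences use the
Euclidean norm with a Theiler window equal to τ. The threshold ε is
calibrated by bisection (seeded by a distance-subsample quantile) until the
recurrence point density over valid pairs lies in [4.5%, 5.5%], targeting
5%; failure to converge raises an error carrying the ε-vs-density trace.
DET is the fraction of recurrent points on diagonal lines of length ≥ 2
(counted on the upper triangle beyond the Theiler band); LAM the fraction
on vertical lines of length ≥ 2 (full matrix). Distances are computed via
a float32 Gram-matrix formulation; line counting is numba-compiled.

## Matching and univariate comparison

The propensity model is a maximum-likelihood logistic regression of faller
status (≥ 1 fall in 12 months) on eight covariates. Small cohorts with
several binary covariates can separate; on separation or non-convergence
the fit falls back to a light ridge penalty (λ = 1e−4 on standardized
covariates, intercept unpenalized) with a warning, and coefficients are
mapped back to the raw scale. Matching is greedy 1:1 nearest-neighbor
without replacement on |logit PS| distance, caliper 0.2·SD of the logit
scores, treated processed in descending PS order (the common default; the
order is pinned and configurable because it changes results), ties broken
by input order. Balance is reported as absolute SMDs (pooled-variance
denominator; pooled Bernoulli variance for binary covariates) before and
after matching. Matched comparisons use Welch's t-test with Satterthwaite
degrees of freedom, interpreted descriptively without multiplicity
correction; a Benjamini–Hochberg column is emitted as clearly-labeled
optional extra output. Sensitivity analyses on the full cohort: OLS of
each metric on group plus the eight covariates (adjusted estimate), and
PS-quintile stratification with stratum-size-weighted group differences
(strata lacking both groups are dropped once, with a warning).

## SHAP under repeated cross-validation

Cross-validation is stratified 5-fold repeated 30 times (150 splits per
condition), with per-repeat shuffle seeds derived deterministically from a
base seed. Per split, features are centered/scaled with training-fold
statistics, constant columns dropped with a warning, and a logistic model
fit with ridge penalty λ = 1 on the standardized scale (sklearn C = 1/λ):
with ~28 predictors and often fewer than 20 training-fold fallers, an
unpenalized fit is unstable or separable, so mild regularization is a
prerequisite for the procedure to run at all; λ is a config knob.
Shapley values are estimated by permutation sampling: each of 64
simulations draws a random feature permutation and a training-set
background row per subject, and walks the permutation flipping one feature
at a time from background to subject value, so one pass yields every
feature's marginal contribution. The estimate averages these contributions
on the predicted-probability scale by default; the link (log-odds) scale is
available, where the model is additive and the estimator converges to the
exact solution β_j·(z_j − z̄_j), which the tests exploit. Standardization
statistics, the model, the Shapley background and the feature ranking all
come from the training fold only; test folds are used exclusively for
out-of-fold prediction. Stability is the fraction of completed splits in
which a feature ranks in the top 5 by mean |SHAP| (ties broken by stable
sort), so the stability column always sums to exactly 5. Undefined feature
cells are mean-imputed per condition before the multivariate stage (counts
recorded in the manifest); the univariate stage instead drops missing
values per metric.

## Synthetic data: what it emulates, what it does not

Signals are a variance-weighted mix of (i) an exactly discretized
Ornstein–Uhlenbeck walk — bounded diffusion with stationary SD σ (cm),
relaxation time τ (s) and closed-form planar MSD `4σ²(1 − e^{−Δt/τ})`,
giving the two-regime diffusion structure SDA expects; (ii) colored noise
with a prescribed DFA exponent via spectral synthesis (power-law spectrum
`f^{−(2α−1)}`, complex-Gaussian coefficients); and (iii) an optional 0.3 Hz
sinusoid carrying a chosen fraction of total variance, which drives
regularity (RQA/entropy). Defaults (σ = 0.35 cm, τ = 1 s, noise SD
0.06 cm) produce sway-plausible magnitudes; eyes-closed trials amplify
σ ×1.3 and noise ×1.2, mimicking the usual vision-removal effect.

Cohorts draw subject-level parameters from log-normal/clipped-normal
population distributions, so features vary realistically between subjects.
Fallers' ages shift by `confound_strength` age-SDs (base age ≈ N(72, 6.5),
floored at 60); medication count and illness probability drift mildly with
age, giving the propensity model real structure. Fall counts for synthetic
fallers are drawn from {1, 2, 3} with probabilities {0.8, 0.15, 0.05},
reflecting the scarcity of recurrent fallers in community cohorts and
exercising the recurrent-faller counting path. Group effects on named
features are injected by shifting the generator parameter that drives the
feature; the per-feature gains were calibrated once by regressing each
extracted feature on the standardized log-parameters across a heterogeneous
population (120 subjects) and inverting the slope, and are frozen in
`EFFECT_MECHANISMS`. Because one physical parameter drives several related
metrics, a planted effect moves a *family* of features (e.g. more
measurement-band noise raises scale-1 entropy but also FD and lowers
DET/LAM) — which is exactly how real interventions behave, and which the
tests' tolerance bands (realized effect within roughly ±0.3 SD of the
request) reflect. The generator is not a biomechanical inverted-pendulum
model: it reproduces the statistical signatures the estimators measure,
not muscle–sensor physiology, so passing tests validate the estimators and
the statistical machinery, not any physiological claim.

Seeding is counter-based per (group, subject, condition, trial) via
`numpy.random.SeedSequence` spawn keys, so enlarging a cohort never
reshuffles existing subjects, and a single global seed reproduces a full
pipeline run bit-identically (verified by manifest checksums).

## Problem sizes and defaults

The default `RunConfig` simulates 8 fallers and 16 non-fallers with 3
trials per condition (144 trials of 6000 samples), a deliberately compact
cohort that exercises every pipeline path — including matching attrition
and small-fold CV — while a full run completes in a few minutes on one
CPU. The CV protocol itself is never scaled down: 5 folds × 30 repeats =
150 splits per condition. Published cohort-dependent counts (e.g. group
sizes of a specific public dataset) are reproduced only when that dataset
is supplied via `trials_dir`/`metadata_path`.

## Known limitations

* The MFREQ constant, MT3 reading, SDA fit windows/coordinates, matching
  order and SHAP output scale are pinned choices among defensible
  alternatives; all are exposed as config knobs and changing them changes
  numbers.
* Plugin AMI and histogram MI are biased for short series; the bias-floor
  rule assumes roughly 6000 samples with 32 bins.
* The Monte-Carlo Shapley estimator is unbiased but noisy at small
  `n_sim`; rankings from very small training folds are intrinsically
  unstable, which the stability table is designed to expose rather than
  hide.
* Mean imputation before the multivariate stage is simplistic; undefined
  cells are rare in practice (flagged sway-density or entropy values) and
  counted in the manifest.
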