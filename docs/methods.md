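# Methods

This note records the statistical model behind `dosurv`, the conventions
fixed where several were defensible, and what the synthetic study design
does and does not establish.

## Cohort and outcome model

The synthetic generator emulates a long-follow-up survivorship cohort. Each
patient carries sex, an age-at-diagnosis category (0–5 / 6–10 / 11–15 / >15
years, multinomial with probabilities 0.539 / 0.202 / 0.213 / 0.046), a
one-hot first-cancer diagnosis group over 42 categories with mildly skewed
group sizes (weights ∝ 1/(1+g), so a few groups are rare enough to exercise
the exact-test branch of the indicator screen), and two binary chemotherapy
exposures (anthracyclines, P = 0.35; alkylating agents, P = 0.55).

Event times follow a Weibull proportional-hazards model

  S(t | X) = exp( −(t/λ)^k · exp(βᵀX) ),

with shape k = 2.2 (the cardiac hazard rises with attained time) and the
default log-hazards β = {mean heart dose: 0.08 per Gy, anthracyclines: 0.9,
alkylating agents: 0.35, one diagnosis group: 0.7}. Censoring is drawn
independently as C = min(U(2, 62), 60) years (administrative horizon 60 y,
median follow-up ≈ 31 y). The baseline scale λ = 219.5 years was solved
once from the analytic event-rate equation

  E[1 − exp(−(C/λ)^k e^{βᵀX})] = 0.05

by root finding over a 2-million-draw sample of the covariate and censoring
distributions, so the default generator realizes the 5%-event / 95%-censor
design; an optional covariate-dependent censoring mode is deliberately not
the default (censoring independent of covariates keeps the IPCW estimators'
assumptions exactly satisfied, which is what the metric tests need).

Inverse sampling T = λ(−ln U · e^{−βᵀX})^{1/k} gives exact draws. All
randomness flows through per-patient `SeedSequence([seed, hash(patient_id),
stream])` streams, so cohorts are bit-identical whether generated in a
batch or streamed, and covariate/outcome draws do not depend on whether
dose volumes are materialized.

## Dose fields and anatomy

Whole-heart masks are random ellipsoids on a 2 mm isotropic grid with
per-axis extents drawn as min + (max−min)·Beta(1.2, 3) (defaults: max
(67, 70, 71) voxels, matching the largest heart extents the analysis has to
accommodate; the skewed Beta keeps typical extents near the cohort mean).
The myocardium is the outer ellipsoidal shell; the interior is split by the
left/right and base/apex midplanes into the four chambers — subparts are
pairwise disjoint, tile the heart, and are always non-empty. Dose fields
are sums of 1–3 anisotropic 3D Gaussian "beams" centred at random in-mask
voxels plus clipped white noise, rescaled so the sessions inside the
six-month summation window sum to a prescribed whole-heart mean dose. The
cohort mean-dose distribution is a 45% point mass at zero (the
non-irradiated majority) and a lognormal(−0.5, 2.0) tail truncated at
48 Gy, reproducing a heavily right-skewed exposure with a median well below
1 Gy. Courses have 1–3 sessions with start offsets cumulated from
U(20, 160) days, so some later sessions fall outside the 183-day summation
window and are deliberately ignored by preprocessing. What this anatomy is
*not*: a realistic heart shape or beam geometry; texture features computed
on it are statistically exercised, not clinically meaningful.

## Preprocessing conventions

Sessions starting within 183 days (inclusive) of the first treatment are
summed voxelwise; later sessions are left out. Outliers are clipped at D₂,
the 98% quantile of in-heart voxel doses, computed as the order-statistic
("lower") quantile: the threshold is then an observed dose and clipping is
exactly idempotent — a linearly interpolated quantile would drift downward
on reapplication. The quantile is computed once over the whole heart and
applied before any per-subpart extraction. The D_x dose-volume indicators,
by contrast, use the linearly interpolated quantile (the numpy default),
which is the common convention for reporting DVH statistics.

## Feature extraction

Doses are discretized with a fixed 0.5 Gy bin anchored at the in-mask
minimum: level = floor((d − min)/0.5) + 1. Anchoring at the minimum makes
all level-based features invariant to constant dose offsets; a value
exactly on the top bin edge opens a new level (the floor convention of the
worked examples). The 93-feature panel decomposes as 18 first-order + 24
GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM, the default feature classes
of the standard radiomics tooling — the only decomposition consistent with
the printed totals (18 and 93). All texture families use distance-1,
26-connected neighbourhoods (13 unique directions); GLCM matrices are
symmetric and GLCM/GLRLM features are computed per direction and averaged.
Gray-level weights in the formulas are the actual level values with absent
levels dropped. Degenerate single-level regions are kept finite by
convention: entropies 0, uniformity/energy 1, correlation-type GLCM
features (correlation, MCC) 1. Directions along which a region has no voxel
pair are excluded from the GLCM average.

The 24 dose-volume indicators are D_x for x ∈ {2, 5, 10, 20, 30, 40, 50,
60, 70, 80, 90, 98} (minimum dose to the hottest x% of the region, i.e. the
(100−x)% dose quantile) and V_d for d ∈ {1, 2, 5, 10, 15, 20, 25, 30, 35,
40, 45, 50} Gy (percentage of region volume at or above d). The grid covers
every indicator the analysis singles out (D₂, D₇₀, V₂) and totals exactly
24.

## Screening

Three train-set-only stages: (1) constant columns and exact duplicates
(pairwise correlation 1 within 1e−12) are dropped, keeping the earlier
column; (2) each diagnosis indicator is tested against the event in a 2×2
table — Fisher's exact test when the exposed-with-event cell has fewer than
10 patients, Pearson chi-square without continuity correction otherwise —
and kept at p < 0.01; (3) dosiomics columns are clustered per region by
complete linkage on 1 − Kendall τ-b and cut at 0.2, which guarantees τ ≥
0.8 within clusters. Each multi-member cluster is represented by the member
with the largest hazard ratio in a multivariate Cox model on the
standardized members (per-SD hazard ratios; otherwise column scaling would
decide), with a univariate fallback when the near-collinear multivariate
fit does not converge; ties break to the earlier column. A fitted screening
result is a pure column selection and is applied to test data without
recomputing anything.

## Models

*Cox PH.* Partial likelihood with Efron tie handling, maximized by a
damped Newton solver with step halving; standard errors from the inverse
observed information; Breslow baseline cumulative hazard attached, so
S(t|X) = exp(−Λ₀(t)·e^{βᵀX}). The solver is validated against lifelines
and scikit-survival on well-conditioned designs. (lifelines' own optimizer
was found to misconverge silently on the heavily right-skewed dose
covariate this package routinely produces — it reported a coefficient ~140
standard errors from the score-equation zero with a *worse* partial
likelihood — which is why the package carries its own maximizer.)
Near-collinear designs are retried with an L2 stabilizer of 1e−6 then 1e−4
times the event count, recorded in the model metadata.

*Cox Lasso.* L1 path via scikit-survival's Coxnet on standardized columns;
the cross-validated partial-likelihood deviance uses the
Verweij–van Houwelingen construction (fold contribution
−2[ℓ(β₋ₖ; all) − ℓ(β₋ₖ; train₋ₖ)]); the penalty is the largest one within
one standard error of the minimum (the `lambda.1se` rule); the surviving
features are refitted without penalty on the original scale. An empty
selection yields a baseline-only model rather than an error, so
cross-validation never aborts.

*Cox Bootstrap Lasso.* Per bootstrap resample: fit the Lasso path, locate
the deviance-minimizing penalty, then walk toward larger penalties and keep
the sparsest feature set whose unpenalized refit is not rejected against
the reference refit by a likelihood-ratio test at level 0.05 with df equal
to the feature-count difference (the level and df convention are fixed
here; nesting is taken by feature counts). Features selected in ≥ 90% of
100 bootstraps enter a final unpenalized Cox fit on the whole train set.
Rows are put in index order before resampling, so selection frequencies are
invariant to row shuffling. Bootstrap resamples with fewer than two events
are redrawn and counted.

*Random survival forest.* scikit-survival's implementation (log-rank
splits, bootstrap per tree); predictions are step-interpolated ensemble
survival curves; the risk score is the expected cumulative hazard.
Hyperparameter tuning maximizes the mean cross-validated Harrell C over a
grid ordered simple-to-complex (ties keep the simpler point); the default
grid is n_trees 500, mtry ∈ {√p, p/3}, min node size ∈ {50, 15, 5}.

## Performance estimation

The censoring distribution G is estimated on training data only: reverse
Kaplan–Meier by default (same-time events leave the risk set before the
censorings at that time are counted; evaluation is right-continuous — the
exact conventions of the scikit-survival estimators, against which the
implementations are verified to 1e−6), or a Cox model for censoring on sex,
age category and the two chemotherapy flags (the clinical covariates minus
the diagnosis group), with Kaplan–Meier fallback. The IPCW concordance
weights event members of a pair by 1/Ĝ(T)²; the bounded C_τ discards events
from τ onwards. Weights can be capped at their 99th-percentile (the
default) as a guard against Ĝ → 0; the canonical uncapped estimator is
available (`weight_cap_quantile=1`) and is what the reference-equivalence
tests use. BS(τ) uses the standard censoring decomposition, and the IBS is
the trapezoidal integral over the 1–60-year yearly grid normalized by the
grid span, truncated (with a warning) where the grid leaves the follow-up
support.

Cross-validation is event-stratified 5-fold (per-fold event counts differ
by at most one). Within an experiment all 16 configurations share one fold
assignment, so the fold-wise rank-sum comparisons are paired and the
per-fold screening is computed once per feature set rather than once per
model. With 5 folds per arm the exact two-sided rank-sum test cannot reach
p < 0.05 (minimum attainable 2/252 ≈ 0.008 only in the most extreme
arrangement; typical fold overlaps give far larger values), so these
p-values are read descriptively. Bootstrap error curves refit each model on
100 (desk: 20) resamples with tuned hyperparameters held fixed and trace
BS(τ) and C_τ on the out-of-bag patients; horizons with no usable
out-of-bag information are flagged missing and excluded from mean curves.

## Execution profiles

The `desk` profile sizes the full 16-configuration experiment for a single
CPU: 2000 patients, dose grids capped at 26×28×28 voxels, a 30-penalty
Lasso path (20 penalties with a relaxed coordinate-descent tolerance inside
the bootstrap selection), a single stratified 75/25 holdout for the
within-bootstrap penalty-error estimate, 20 stability-selection bootstraps,
and a fixed coarse RSF point (40 trees, min node 50). The `paper` profile
keeps the
full design (7367 patients, full-size grids, 5-fold inner selection, 100
bootstraps, the full RSF tuning grid) and is compute-bound but supported.
The desk numbers are internally consistent comparisons, not estimates of
the full-scale operating characteristics.

## What the synthetic design shows — and does not

Passing tests establish that the pipeline's machinery is correct: features
match independent brute-force enumeration, metrics match independent
reference implementations, Cox fits recover the generator's coefficients,
screening guarantees its correlation bound, stability selection finds
planted signals, the null configuration is calibrated at C ≈ 0.5, and the
whole experiment is byte-reproducible from one seed. They do not establish
clinical performance: the generator's hazard is exactly proportional, its
censoring exactly independent, its dose fields anatomically naive, and its
texture content arbitrary — so absolute C-index or Brier levels on
synthetic cohorts say nothing about real patients, and relative model
rankings reflect the generator's simplicity (a mean-dose Cox model is close
to well-specified here by construction).

## Numerical conventions worth knowing

- Quantile estimators: order-statistic for the clipping threshold (exact
  idempotence), linear interpolation for D_x and first-order percentiles.
- Exact duplicates are detected at correlation ≥ 1 − 1e−12.
- Kendall τ is τ-b (tie-corrected), as discretized features tie often.
- Partial-likelihood evaluations shift the linear predictor by its maximum
  before exponentiating (overflow-safe; cancels exactly).
- Degenerate bootstrap draws (constant columns) drop those columns for
  that resample only.
- The NIfTI writer stores doses as float32; round-tripping through disk is
  exact to ~1e−7 relative.
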