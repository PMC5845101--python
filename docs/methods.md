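# Methods

This note documents the models and procedures `ehrmiss` implements, the
defaults and why they were chosen, the numerical decisions that matter, and
what the synthetic-data tests do and do not establish about real EHR data.

## Synthetic population model

Real lab values per patient are modeled Gaussian-copula style: one latent
draw `z ~ N(m, R)` per patient, pushed through a monotone per-variable
marginal transform. `R` is a block correlation matrix — `rho_within` inside
each panel, one `cross_panel_correlation` elsewhere — checked for positive
definiteness at construction. The latent mean `m` shifts linearly with
standardized age, BMI, and a sex indicator (per-variable coefficients,
default zero). The marginal transform is `x = exp(s·z)` for skew exponent
`s > 0` (positive, right-skewed support, as lab assays typically are) or the
identity at `s = 0`. A monotone transform preserves rank correlations, so
correlation-recovery tests can be run exactly on the latent scale.

Observation is decided per panel, not per cell, because lab panels are
ordered jointly: `logit P(panel observed) = intercept + b_age·z_age +
b_sex·male + b_bmi·z_bmi + b_value·(panel mean latent)`. The covariate terms
form an MAR channel, the `b_value` term an MNAR channel; independent
cell-level dropout can be layered on at a configurable rate. Each observed
(patient, variable) pair receives `1 + Poisson(mean − 1)` dated records,
jittered uniformly within ±365 days of a patient anchor date, with latent
measurement noise (sd 0.1) across repeats. Dates are integer day offsets
from 1970-01-01 throughout; the I/O layer renders ISO-8601.

Default fixture: 28 variables named by LOINC code, grouped CBC (11) /
chemistry (13) / lipids (4), with within-panel correlations 0.4 / 0.3 / 0.5,
cross-panel 0.1, skew 0.4, high observation probabilities for CBC and
chemistry and a covariate-driven (age/sex/BMI) lipid-screening model. The
correlation values are chosen for testability — strong enough that
conditional imputation demonstrably beats marginal fills, weak enough that
the matrix is comfortably positive definite; they are not calibrated to any
specific health system.

**What the generator does not emulate:** unit heterogeneity and assay
migrations, detection limits and censoring, informative visit timing,
comorbidity-driven test batteries, inpatient/outpatient mixtures, and
non-Gaussian dependence (tail dependence) between panels. Passing tests
demonstrate correctness of the machinery and the theoretically expected
behavior of methods under controlled mechanisms — not performance claims
about any particular real dataset.

## Preprocessing

Events are kept when the patient is between their 18th and 90th birthdays
(ages in exact days / 365.25) and, when a death date exists, only up to 365
days before it — observation frequency and values both shift in the final
year of life, so that window is excluded along with post-death records.
Variables observed in fewer than 0.5% of patients (default) are dropped.
Each patient's median event date defines a ±1,826-day (5-year) window;
events outside it are discarded and the cell value is the median of the
rest (even counts: midpoint). Medians are order-invariant and robust to the
occasional extreme value the generator's noise model produces.

Each variable is then Box-Cox transformed and Z-standardized on its observed
cells. Non-positive support is shifted by `1e-6 − min` first. The exponent λ
maximizes the profile log likelihood (`scipy.stats.boxcox_llf`) over
λ ∈ [−3, 3] by bounded scalar minimization with tolerance 1e-4; the bounded
search keeps pathological columns from driving λ to extreme values.
Standardization uses the sample sd (ddof = 1); constant columns are an
error. All parameters (λ, shift, mean, sd) are stored per variable, and the
transform round-trips to 1e-6 relative error. The transform is fit globally,
not per sex stratum: downstream benchmarking operates on one pooled matrix
and a global fit keeps the inverse transform unambiguous.

## Missingness diagnostics

The ranking table sorts variables by missing count (ties by name) and
reports, at each rank r, the percent of patients missing that variable and
the percent complete for *all* variables of rank ≤ r — both exact
counts-over-n. Choosing how many variables to impute is left to the user:
that decision mixes statistics with clinical judgment.

Presence prediction: the target's observation mask is the label; features
are the values of all variables outside the target's panel (co-panel
members would leak the label through joint ordering). Missing feature cells
are mean-imputed inside each training fold with accompanying
missing-indicator columns — the indicators let the forest exploit
correlated missingness without conflating it with the filled values.
Stratified k-fold (default 10) with a 100-tree random forest per fold;
AUROC is computed by the trapezoidal rule (ties get half credit, making it
identical to the concordant-pair fraction) and averaged over folds.

## Complete cases and matching

Complete-case extraction is a row filter over a designated variable set
(vacuously all rows for an empty set). Representative matching samples `n`
patients without replacement and pairs each with the complete case of
identical sex minimizing Euclidean distance on age and BMI Z-scored against
the *population* (unscaled units would let age dominate). Matches are drawn
with replacement — one complete case may represent several sampled patients
— and distance ties break to the lowest patient id so results are exactly
reproducible. The default sample size scales with the fixture rather than
any fixed count.

## Amputation

All mechanisms operate on a complete truth matrix, return the truth plus a
boolean removal mask, and never modify the truth, so unmasking is exact.
Per-dataset RNG streams are derived by hashing the mechanism parameters
together with the master seed, making grids reproducible and independent of
generation order.

- MCAR: each cell removed independently with probability p; the grid runs
  10 replicates at each of 10–50% (50 datasets).
- MAR: rows whose column-A value lies in a chosen quartile lose their
  column-B value with probability `frac` (default 0.5); the grid covers
  every ordered pair and quartile — V(V−1)·4 datasets, 3,024 at V = 28.
  Ordered pairs (not unordered) are what that count fixes.
- MNAR: cells of a column whose own value lies in the quartile are removed
  with probability `frac`; V·4 datasets, 112 at V = 28.
- Realistic: each complete case inherits the observed/missing pattern of
  its nearest population neighbor (sex exact, standardized age/BMI,
  self-matches excluded, ties to lowest id). Deterministic by construction.

Quartiles use empirical quantiles at 0.25/0.5/0.75; a value exactly on a
boundary belongs to the lower quartile. `frac` generalizes the 50% removal
rate; 0.5 is the default and the grid setting.

## Imputation methods

Eleven methods in three families. Observed cells pass through bitwise
unchanged in every method; all stochastic streams derive from one seed.

**Simple fills.** Mean and median use the per-variable observed statistic.
Random sampling fills each missing cell with a uniform draw from the
column's observed values, independently per copy. On standardized data its
RMSE tends to √2 — the root of `E(X − X′)² = 2σ²` — which is the benchmark
floor any model-based method should beat.

**k-nearest neighbors.** Row distance is the Euclidean distance over
jointly observed variables divided by √(number shared) (an RMS per shared
coordinate, so sparse and dense row pairs are comparable); a missing cell is
the mean of the k nearest rows that observe the variable, skipping
neighbors that lack it and falling back to the column mean (logged) when no
comparable row has it. O(n²) memory in the distance matrix — appropriate at
benchmark scale, not for very large cohorts.

**Low-rank completion.** Both variants iterate: SVD of the column-centered
filled matrix → modified spectrum → refill missing cells, until the
relative change of the filled cells is below `tol` (default 1e-4) or
`max_iter` (default 100) sweeps, which sets a non-convergence flag.
`svd_iterative` keeps a fixed `rank`; the rank is grown one component at a
time with warm starts, because cold-starting at the full target rank leaves
spurious components the iteration cannot remove (a bad-stationary-point
failure mode observed directly in development). `soft_impute` shrinks
singular values by λ; because a small λ moves the iterate only O(λ) per
sweep, λ is annealed along a warm-started geometric path (factor 0.3) from
just below the leading singular value down to the target, and the solution
is then debiased by re-running with hard truncation at the rank the soft
solution retained — components below 2% of the leading thresholded singular
value are treated as annealing residue, not structure. The 2% cutoff means
genuinely tiny components (contributing < 2% anyway) may be dropped by the
debias step. λ at or above the leading singular value reproduces mean
imputation exactly. Note that completion is only identifiable where each
row retains at least (rank) observed cells; rows below that are filled at
the column mean implicitly.

**Chained equations (fully conditional specification).** Missing cells are
initialized, then each incomplete variable — visited in ascending order of
missingness — is regressed with intercept on its allowed predictors'
current completed values and refilled by the per-variable rule; the cycle
repeats `iterations` times (default 10, deliberately above common library
defaults) and `m` chains run independently (default 5). The predictor
matrix excludes pairs with absolute pairwise-complete correlation above
0.85 (near-duplicate assays make the regressions ill-conditioned) and the
diagonal; singular designs fall back to a 1e-6 ridge, logged. Per-iteration
mean absolute changes of the imputed cells are recorded as convergence
diagnostics but not formally tested. Fill rules:

- `norm_predict`: OLS predicted mean (deterministic);
- `norm`: Bayesian linear regression — σ² drawn as RSS/χ²(n−p), β from
  N(β̂, σ²(XᵀX)⁻¹), plus N(0, σ²) residual noise;
- `pmm`: predictive mean matching — one posterior draw gives predicted
  means for observed and missing cases; each missing case takes the
  observed value of a donor chosen uniformly among the `d` = 5 nearest
  predicted means (pool reduced, with a log message, if fewer observed);
- `rf`: a random forest (10 trees, minimum leaf 5) fit on observed cases;
  each missing case draws one tree uniformly and samples uniformly among
  the observed values in that tree's terminal node (pmm fallback if the
  forest degenerates);
- `col`: a single deterministic column-wise OLS pass from mean-initialized
  data — a one-sweep counterpart to `norm_predict`.

The deterministic rules (`norm_predict`, `col`) initialize missing cells
with column means and run a single chain replicated m times; the stochastic
rules initialize with random draws from the observed values, one stream per
chain. A literal reading of "initialize randomly" for every rule would make
the nominally deterministic rules chain-dependent; mean initialization is
what makes their determinism exact and reproducible, which is the property
that matters for the multiple-imputation taxonomy.

Determinism classes: {mean, median, knn, svd_iterative, soft_impute,
ce_norm_predict, ce_col} produce identical copies (zero between-imputation
variance); {random_sample, ce_norm, ce_pmm, ce_rf} produce genuinely
different copies.

## Evaluation

RMSE is computed over amputed cells only, overall or per variable; an empty
mask yields "absent" (NaN per variable, an error overall), never zero.
Calibration requires m ≥ 2: per variable, `x` = mean over copies of
RMSE(copy, truth) and `y` = mean over copy pairs of RMSE(copyᵢ, copyⱼ),
both at masked cells. The mean deviation from unity is defined here as
`MD = mean over variables of (x − y)` — signed, so positive MD means the
spread between imputations understates the actual error
(under-dispersion); deterministic methods have y ≡ 0 and MD equal to their
mean per-variable error exactly. This definition is recorded in the report
metadata since other summaries of the (x, y) cloud are possible. For a
correctly calibrated stochastic method both x and y estimate
√2·(conditional sd), so MD ≈ 0.

The benchmark driver crosses datasets with method configurations, isolates
failures per (dataset, method) cell — a method failing on one dataset is
recorded and the sweep continues — and emits a tidy table with aggregate
and optional per-variable rows.

## Pipeline and formats

All artifacts are delimited text: long events and demographics with
ISO-8601 dates (empty field = absent death date), wide matrices with empty
cells for missing, masks as 0/1. Readers parse floats in round-trip mode,
and files the package writes re-read and re-write byte-identically. Errors
name the file, line, and offending value. The pipeline driver derives one
seed per stage from the master seed by stable hashing, validates stage
dependencies before execution (e.g. `impute` requires `ampute` or an
explicit masked input), and writes a manifest of SHA-256 checksums so reruns
can be verified identical.

## Problem sizes and limitations

The shipped tests and the reproduction script use a 5,000-patient synthetic
population for the presence-prediction diagnostics, ~10⁴ masked cells for
the RMSE-limit checks, 800×6 and 2,000×2 matrices for calibration and
moment-recovery checks, and toy matrices for exact oracles — sizes at which
every expected effect is comfortably detectable and a full run completes in
about a minute on one core. Larger populations change nothing structurally.

Known limitations: no categorical-variable support (the benchmark targets
are numeric lab values); no mixed/weighted amputation mechanisms; no
statistical testing across methods; chained-equation convergence is logged,
not proven; the knn distance matrix is quadratic in patients; and the
generator's realism caveats above apply to any conclusion drawn from
synthetic fixtures.
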