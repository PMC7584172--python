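# Methods

This note documents the models, the synthetic data that stands in for
restricted Medicare claims, the numerical choices, and the limits of
what the packaged experiments demonstrate.

## Outcome model and the standardized readmission ratio

The unit of analysis is the hospital. For each specialty cohort
(medicine, surgery/gynecology, cardiorespiratory, cardiovascular,
neurology) we fit a random-intercept logistic regression to eligible
index admissions,

logit P(y_hi = 1) = β₀ + β₁(age_i − 75) + β₂(comorbidity_i − 2)
+ Σ_d β_d 1[dx_i = d] + α_h, with α_h ~ N(0, τ²),

by maximizing the marginal likelihood. The per-hospital integral is
approximated with Gauss–Hermite quadrature *adapted* to each hospital's
posterior mode and curvature (9 nodes by default). Unadapted quadrature
fails for large clusters because the integrand concentrates far from
zero; the adaptive rule keeps the approximation accurate at any cluster
size. On a 90,000-record fixture the estimates agree with lme4's
`glmer` at the same quadrature order to about 1e-5 in coefficients,
standard errors, τ̂, and log-likelihood (a dual-route test in the
suite). τ is optimized on the log scale with a lower bound, so a
no-between-hospital-variance solution surfaces as τ̂ ≈ 0 rather than as
an optimizer failure. Hospitals whose discharges are all events or all
non-events are flagged; their α̂_h are the shrunken posterior modes, so
no separate fallback is needed.

A hospital's cohort SRR is predicted over expected readmissions: both
are sums of inverse-logit probabilities over the hospital's eligible
discharges, the numerator with the hospital's own shrunken effect α̂_h,
the denominator with the average hospital effect. "Average" defaults to
the unweighted arithmetic mean of the α̂_h (the phrase "average effect
of all hospitals" reads as a mean over hospitals, not the random-effect
distribution mean); `weighted_mean_alpha` (volume-weighted) and `zero`
(distribution mean) are config options. With the volume-weighted
option, the volume-weighted national mean of log SRR is ≈ 0 by
construction — a calibration invariant the suite checks to ±0.02.

Cohort SRRs combine into the hospital-wide value as a volume-weighted
logarithmic mean (equivalently, a volume-weighted geometric mean);
cohorts where the hospital has no eligible discharges carry zero weight
and are skipped. Downstream analyses use the log-scale value
`combined_log_srr` as the regression outcome. Multiplying the combined
SRR by the national observed rate (default: the eligible-discharge
readmission rate of the input data) gives the standardized rate in
percent.

## Synthetic data: what it emulates, what it does not

The generator produces four tables — geography (zip→county with
populations, including a configurable fraction of zips spanning two
counties), community values, hospitals, and discharges — from one
global seed with named substreams, so any stage can be regenerated
alone and identical configurations are byte-identical.

Community variables follow the packaged 71-variable, 6-domain catalog
(10/13/19/15/10/4 variables per domain; five nursing-home/home-health
quality variables at the zip level, the rest at county level).
Within a domain, variables share a latent county factor giving pairwise
correlation `within_domain_rho` (default 0.3); marginals are standard
normal, and engineered near-duplicate pairs (r > 0.99) can be requested
to exercise redundancy elimination. Patient outcomes follow
logit p = μ + α_h + γ'x + β'z(zip), with exposures standardized before
β is applied so effects are comparable across variables (log-odds per
SD). Default μ = logit(0.153) targets a 15.3% baseline readmission
rate; default τ = 0.3; patient effects default to 0.02/year of age,
0.15 per comorbidity, and diagnosis-category offsets (0, 0.25, −0.2,
0.4) — moderate, plausible magnitudes. Exclusion flags (planned index
admission 3%, transfer 2%, died/hospice/against-medical-advice 5%) are
independent Bernoulli draws; the planned-readmission determination
itself is collapsed into the outcome label and the flag.

Each hospital draws patients from a home county with a 20% "leak" to
the whole map, which is what makes hospital-level mean exposures vary:
with hospitals spread across counties (the default pairs each hospital
with its own county), exposure means differ across hospitals roughly
like the county values themselves. Real claims differ in many ways the
generator does not attempt: ICD-coded cohort assignment, realistic
comorbidity structure, spatial autocorrelation beyond the single county
factor, volume-outcome correlations, and measurement error in the
community sources. Passing tests therefore demonstrate the *machinery*
— estimation, linkage, screening, selection — not the substantive
findings one would obtain on claims.

## Forest screening

Trees are regression trees with greedy variance-reduction splits,
restricted to 3 variables sampled per tree (a per-node sampling option
exists), each trained on a random half-sample and validated on the
other half (validation R² is recorded per tree but does not enter the
importance). Importance is the proportion of root-to-leaf decision
paths passing through a split on the variable, pooling all trees; a
path through k distinct variables credits each once, and scores are
normalized to sum to 1. Independent brute-force enumerations pin both
the split search and the path counting in the test suite.

Trees are kept deliberately small: minimum node size 5 hospitals and a
depth cap of 3 (default). The ensemble-of-small-trees design is what
gives path-proportion importance its discriminating power — with
unbounded depth nearly every path in a 3-variable tree eventually
passes through all three variables, so importance degenerates toward
the uniform sampling frequency and true signals are not separated from
noise. At depth ≤ 3 a signal variable claims the root (hence every
path) while noise variables split only below it. `max_depth=None`
restores unbounded growth for sensitivity analysis. Forest inputs are
the continuous hospital mean exposures (quintilization is for the
regression stages); missing exposures are mean-imputed with a logged
count.

## Weighted models, Wald tests, collinearity

All explanatory models are hospital-level weighted least squares on
indicator-coded quintiles (Q1 reference), weighted by the readmission
denominator volume. R² is the weighted 1 − SSE/SST about the weighted
mean; adjusted R² uses n = hospitals and p = indicator columns. The
joint Wald statistic per variable is b'V⁻¹b on 4 df against a
chi-square reference (an F option exists for small samples). Belsley
diagnostics scale all columns — intercept included, per standard
practice — to unit length, take the SVD, and compute condition indices
and variance-decomposition proportions; a component is flagged at
condition index ≥ 20 when two or more coefficients load > 0.50 on it.
For an exactly singular design the proportions are undefined, so flags
fall back to null-space participation; the condition index is reported
as infinite.

Selection proceeds domain by domain: the top-importance variable seeds
the model unconditionally, every further candidate is evaluated in
importance order (ties broken by name), and kept when the relative
adjusted-R² gain (after − before)/max(before, 1e−6) reaches 0.10.
Rejected candidates are not revisited, and evaluation continues through
the full ordered list. An alternative rule retains candidates with
joint Wald P < 0.10, matching the other published description of the
procedure; the R² rule is the default because it is the more specific
one. Redundancy elimination iterates: diagnose the pooled design, drop
the lowest-importance variable in the worst flagged set, repeat until
flag-free — preserving what the screening stage valued most. Both raw
and adjusted R² are always reported, since either may be the value a
reader expects.

## Validation experiments and their design choices

- **Parameter recovery** (300 hospitals × 300 discharges, τ = 0.3,
  5 seeds): τ̂ lands in [0.24, 0.36] in every seed and
  inverse-variance-pooled fixed effects sit within 2 pooled SE of
  truth. Pooling across seeds is the appropriate bias check; per-seed,
  per-coefficient ±2 SE bands would fail by chance for a perfectly
  unbiased estimator.
- **Null calibration** (1000 hospitals, all community β = 0,
  20 replicates): per-variable joint Wald rejections at α = 0.05 land
  at 0.05 ± 0.02, and the final model's adjusted R² stays below 0.05.
  This experiment fixes *equal* hospital volumes. At desk scale
  (~30 discharges/hospital) the log-SRR of a big hospital is *less*
  shrunken and therefore more variable than that of a small one — the
  opposite of the 1/volume variance that volume-weighting assumes — and
  with lognormal volumes that mis-specification alone inflates the
  rejection rate to ~0.25. Equal volumes isolate the property under
  study (the test's nominal size); with claims-scale volumes
  (thousands of discharges per hospital) shrinkage is negligible and
  the issue largely disappears. Under the null the relative-10% rule
  still retains roughly half the candidates (its gains are noise), so
  the *raw* final R² mechanically approaches p/n ≈ 0.08; the adjusted
  value is the meaningful null quantity.
- **Effect recovery** (one ±0.5 log-odds/SD signal per domain,
  300 hospitals, 10 seeds): signal variables reach the final model with
  correctly signed Q5 coefficients in ≥ 9/10 seeds, and retention is
  nondecreasing in |β|.

Experiment sizes (100–1000 hospitals, ≤ 90k discharges, 500 trees) are
desk-scale choices that keep each experiment in minutes; every size is
a config key, so claims-scale runs (thousands of hospitals, millions of
discharges, 10,000 trees) are a configuration away.

## Numerical details and edge cases

- Quintile labels: stable sort, position k gets ⌊5k/n⌋ + 1, tied values
  all take the lowest label in their group; a constant variable
  collapses to Q1 with a warning, fewer than five distinct values warns.
- Tree tie-breaks: equal split scores go to the lower variable index,
  then the lower threshold, so forests are bit-reproducible.
- Optimizer: L-BFGS-B on (β, log τ) with log τ ∈ [−12, 3]; convergence
  tolerance 1e−10 relative on the negative log-likelihood; posterior
  modes warm-started between evaluations; standard errors from the
  numerically differentiated observed information (fixed-effect block
  only when τ is at its boundary).
- Missing community values propagate as missing: hospital means use
  available patients, hospitals missing a variable entirely drop from
  models containing it (count recorded on the fit).
- Degenerate inputs raise informative errors: single-hospital cohorts,
  one-class outcomes, rank-deficient designs (aliased columns named),
  empty retained sets, non-positive weights.

## Known limitations

- The generator's county-factor correlation structure is exchangeable
  within domains; it cannot represent block or spatial structure.
- The marginal readmission rate rises above expit(μ) when large
  community effects are planted (Jensen's inequality), so demo runs
  with strong signals show mean standardized rates above 15.3%.
- Adjusted R² after data-driven selection is still optimistic; the
  packaged experiments quantify this under the null rather than
  correcting for it, mirroring the analysis being emulated.
- The Wald chi-square reference is asymptotic in the number of
  hospitals; for runs with < 100 hospitals the F option is preferable.
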