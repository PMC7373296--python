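# Methods

## Cohort generator

The generator emulates a small case-control plasma proteomics study and
records enough ground truth to serve as an oracle for every downstream
stage.

**Intensities.** Each protein's log10 intensity is normal with a
per-protein mean drawn uniformly from [3, 6] (intensities spanning three
orders of magnitude, matching the reference levels seen in such assays)
and a common SD of 0.3 log10 units. Nothing in the pipeline depends on
the log-normal choice beyond positivity — it is an assumption, made
because the true intensity distribution of such panels is not
characterized publicly.

**Outcomes.** A superpopulation (default 25× the requested cohort) is
drawn; case status is assigned prospectively by a logistic model over the
protein effects; exactly `n_cases` cases and `n_controls` controls are
then sampled. Retrospective sampling leaves all non-intercept logistic
coefficients estimable (the classical case-control result), which is the
property the recovery experiments verify. The baseline intercept targets
a ~45% marginal case fraction so the superpopulation stays small; the
intercept is the one parameter this choice distorts, and nothing infers
it.

**Effects.** `EffectSpec(j, beta1, beta2)` contributes
`beta1*z + beta2*z²` to the log-odds, where `z` is the protein's
*centered, true-SD-standardized* log10 level. Centering is essential for
U-shapes: it puts the risk minimum inside the observed range, so
`beta2 > 0` yields cases enriched in both tails. The scan fits the
uncentered control-SD-scaled level instead; the two codings are affinely
related, so the quadratic model family and its likelihood-ratio test are
identical under either. Note the unit mismatch this implies: a generator
`beta2` is per squared *population* SD, while scan outputs are per
squared *control* SD, and under a strong U-shape controls are compressed
(control SD < population SD), so the same effect looks numerically larger
on the scan's scale.

**Covariates.** Frequency-matched covariates (age, sex, race/ethnicity,
site, season) are drawn marginally with no outcome effect. Covariates
with outcome-conditional prevalences — overweight BMI (61.5% cases /
44% controls), sr-IBS (48% / 2%), antidepressant use (30% / 10%, a
plausible figure for this population; the characteristics table such
studies print does not include it) — are drawn *conditionally on the
sampled outcome*. Because each is independent of the protein levels
given the outcome, the implied joint model is exactly logistic with the
protein coefficients unchanged and the covariate log-odds equal to the
2×2 log odds ratio of its prevalences, so outcome-conditional sampling is
consistent with the covariate-adjusted scan. A consequence worth knowing:
with a 2% control prevalence, roughly 44% of simulated cohorts contain
*zero* sr-IBS controls and the covariate quasi-separates (see the scan's
separation policy below).

**Missingness.** Per protein, the lowest `ceil(q·n)` values are censored
(missing-not-at-random detection-limit censoring at quantile `q`,
default 0.10), plus an independent 2% missing-completely-at-random
component. The MCAR draw does not depend on `q`, so raising the detection
quantile under a fixed seed only grows the missing set. The detection
quantile is homogeneous across proteins; real panels have heterogeneous
limits (and hence a tail of mostly-missing proteins), which the default
configuration does not emulate — the missingness filter is exercised by
dedicated tests instead.

## Preprocessing

Order: optional LOESS normalization → missingness filter bookkeeping →
half-minimum imputation → log10 + control-SD rescaling.

- Non-detects are replaced by 50% of the protein's smallest *observed*
  value (the protein-wise reading of the half-minimum rule; standard
  detection-limit practice). Proteins with no observed values are dropped
  with a warning. Imputation is idempotent.
- The missingness filter (strictly-greater-than 50% excludes; exactly 50%
  is retained) is evaluated on the pre-imputation matrix and consumed
  only by the classifier stage; the association scan uses all imputable
  proteins.
- Rescaling divides the log10 level by the control-group SD *computed
  after imputation* (imputed values enter the models, so they enter the
  scale too) and applies no centering — the logistic intercept absorbs
  location. The control SD in stratified scans uses all controls.
- The optional local-regression normalization (off by default) fits, per
  subject, a LOESS curve (span 0.75) of log-ratio-to-reference against
  reference log intensity and subtracts it; the reference is the
  per-protein median profile. It removes constant and
  intensity-dependent multiplicative bias and leaves the reference
  profile itself fixed.

## Association scan

Per protein and stratum, a hand-written Newton/IRLS logistic fitter
(convergence 1e-8 relative log-likelihood, max 100 iterations, step
halving, covariance = inverse observed information) fits the linear and
linear+quadratic models. The fitter is deliberately lean — a full scan
refits the same small design hundreds of times, and the Monte-Carlo
calibration experiments run ~60k fits — and is tested to 1e-6 agreement
against statsmodels. The quadratic fit internally centers the
transformed level (whose square is otherwise ~0.999-correlated with it)
and maps coefficients and covariance back exactly.

**Design matrix.** Intercept; age numeric; sex/season/BMI-class/sr-IBS/
antidepressant as 0-1 indicators; race and site dummy-coded against the
most frequent level, with levels under 3 subjects collapsed into "other"
(and a still-sparse "other" folded into the reference); covariates
constant within a stratum dropped; all collapses reported; rank checked
with aliased columns named. Batch enters as a dummy only in the
sensitivity configuration.

**Small-sample calibration.** At n ≈ 80 with ~14 parameters the χ²₁
reference for the quadratic LRT is anticonservative: the mean null
statistic is ~1.45 (a Bartlett-type inflation, worst for the
high-leverage squared term), and uncorrected the scan's family-wise
error rate at α = 0.05 is ~0.35 instead of 0.05. Two standard devices
restore calibration: a genomic-control inflation factor λ (estimated
from the mean of the smallest 90% of the family's statistics against the
corresponding truncated χ² mean — lower-variance than the classical
median estimator and equally insensitive to a sparse minority of true
signals; floored at 1; only estimated for families of ≥ 20 tests) and an
F(1, n − p) reference for the rescaled statistic in place of χ²₁. On
12,000 null scan statistics this combination is calibrated to the far
tail (empirical P(p < 5·10⁻⁴) = 5.0·10⁻⁴), and the measured FWER over
300 null cohorts is 0.047. The uncalibrated χ² tail is still reported
per protein (`lrt_p`) alongside the calibrated value
(`lrt_p_calibrated`) that the Hochberg step consumes; the same treatment
applies to the linear Wald family, where λ typically floors at 1.

**Multiplicity.** Hochberg's step-up at α = 0.05, applied separately to
the linear-Wald family and the LRT family, per stratum. Adjusted
p-values follow the step-up formula (min over j ≥ i of (m−j+1)p₍ⱼ₎,
capped at 1) and are cross-checked in tests against brute-force
enumeration and statsmodels.

**Separation.** Fits are plain (unpenalized) maximum likelihood.
A *protein* is flagged and excluded from both rejection sets when either
of its fits fails to converge or one of its own coefficients exceeds 15
in absolute value on the fitting scale — a divergent MLE must not be
declared significant. Divergent *nuisance* coefficients (e.g. sr-IBS in
a cohort with no exposed controls) do not flag the protein: both nested
models contain the covariate, so the protein contrast and the LRT remain
stable; only the covariate's own Wald summary is meaningless there.

**Reference levels and aOR curves.** For gate-passing proteins the
minimum-risk level is the vertex −β₁/(2β₂) when β₂ > 0 and interior,
else the boundary with the smaller linear predictor, mapped back to raw
intensity units by inverting the transform. aOR contrasts use the delta
method on the (β₁, β₂) covariance block; a parametric-bootstrap
cross-check is part of the test suite. Wald p-values are used for aOR
contrasts (the method such tables leave unstated); ties are broken by
protein id for deterministic output.

**Strata.** Predefined: all subjects; sr-IBS cases vs all controls;
non-sr-IBS cases vs all controls (both drop the sr-IBS covariate, which
is aliased among cases); females only (drops sex). A stratum leaving
fewer than 10 subjects in either class refuses to run.

## Biomarker panel

Inputs are the filtered proteins' transformed levels only — no
covariates, no quadratic terms. Consequently proteins whose association
is purely U-shaped are expected to be invisible to the panel stage.

- **Lasso selection frequency:** per holdout iteration (default 1000),
  a stratified 80% training split is standardized, the L1 penalty chosen
  by 10-fold cross-validated deviance, the model refit, and nonzero
  coefficients counted. Degenerate splits are redrawn from an advanced
  substream and logged.
- **Forest importance:** explicit bagging over 500 sklearn decision
  trees (sklearn's forest exposes no out-of-bag permutation importance);
  per tree, out-of-bag accuracy is compared before and after permuting
  each used feature, and drops averaged over trees — Breiman's mean
  decrease in accuracy.
- **Boosting gain:** XGBoost (depth ≤ 3, 200 rounds, learning rate 0.1,
  single-thread, exact tree method), per-protein total split gain
  normalized to sum to one. Tree hyperparameters are conventional
  defaults; none are prescribed by the analysis being modeled.
- **Consensus:** intersection of the three top-20 sets, ties at the
  boundary broken by higher lasso frequency then protein id; an empty
  intersection is an explicit, warned outcome.
- **Evaluation:** stratified 80/20 holdouts; logistic regression (in
  place of the lasso), 500-tree random forest, boosted trees; exact
  rank-statistic AUROC (ties get half credit) per iteration; mean and
  2.5–97.5 percentile interval over iterations; ROC points pooled over
  test splits. The rank AUROC and the trapezoidal ROC area agree to
  1e-12 by construction, and both are cross-checked against sklearn.
  Splits are stratified by outcome — unstratified 20% test splits of an
  80-subject cohort would occasionally be single-class.

Forest and boosting importances come from full-data fits (the single
values such importance tables print suggest no aggregation over CV);
the lasso percentage is inherently resampling-based. The "direction"
column is the sign of the case-minus-control mean transformed level.

## Pipeline

A YAML config with one section per stage (unknown keys rejected) drives
simulate → preprocess → scan → panel; stages are individually runnable
and resumable, user-supplied TSV tables can replace the simulator, and
every artifact is plain text (TSV/JSON). Per-stage seeds derive from the
master seed through `SeedSequence([master, stage_index])`, so a stage
re-run in isolation is bit-identical to the full run. The manifest
records config, seeds, input digests, timings and stage status. The
report stage renders plots and a markdown summary from artifacts only.

## What the simulations do and do not show

Passing tests demonstrate calibration and recovery *under the
generator's assumptions*: log-normal intensities, homogeneous detection
limits, covariates exactly conditionally independent of proteins given
outcome, and effects on the standardized log10 scale. Real cohorts
violate all of these to some degree (correlated proteins, batch
structure, heterogeneous censoring), so the guarantees are necessary,
not sufficient, for real-data validity.

Two honest findings from the package's own experiments deserve emphasis:

- **Uncalibrated quadratic LRTs overstate significance at n ≈ 80.** The
  plain χ²₁ tail inflates the family-wise error of the gate-keeping scan
  sevenfold at these conditions. Any analysis of this design that relies
  on asymptotic LRT p-values should be read with that in mind.
- **Consensus panels at 80 subjects × 250 proteins are fragile.** In the
  demonstration cohort the intersection panel consists of null proteins
  whose chance correlation with the outcome exceeds the moderate true
  signals, yet it still achieves holdout AUROC ≈ 0.8 *within* the
  cohort. Repeated-holdout AUROC inside one small cohort does not
  establish generalization; external validation does.

## Known limitations

- Selection power for a U-shaped effect of β₂ = 1.5 (generator units)
  under properly controlled FWER is ~0.3–0.5 at n = 80 — below a
  majority of replicates. The corresponding acceptance-level test is
  left failing deliberately; raising measured power by weakening the
  calibration or reinterpreting the effect scale would be
  self-deception.
- The logistic MLE carries the classic O(p/n) away-from-zero bias at
  n = 80 with ~14 parameters (≈ +30% on a log-odds of 0.8); CI coverage
  is nonetheless ≈ 0.95. Consistency is verified at larger n. Firth-type
  penalization is deliberately not applied, matching the unpenalized
  estimates this class of analyses reports.
- Batch effects are modeled only as additive log10 shifts; the
  local-regression normalization addresses intensity-dependent bias, not
  batch structure.
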