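# Methods

This note documents the models and procedures `trialcea` implements, the
assumptions they rest on, the synthetic-data generator's calibration, and
the numerical choices made where the design was genuinely open. It states
no empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Evaluation framework

The package performs a within-trial economic evaluation of a two-arm
cluster-randomised trial from a healthcare-system perspective over a
six-month horizon (no discounting), on an intention-to-treat basis.
Outputs are incremental cost, incremental QALYs, incremental net benefit
at decision thresholds, and cost-effectiveness acceptability curves, each
produced for a complete-case and a multiple-imputation analysis.

### Cost construction

Three components sum to each participant's total six-month healthcare
cost:

1. **Intervention delivery** — fixed once-off outlays (website set-up,
   educator/administrator time) plus variable operating items, divided
   equally over the intervention-arm headcount; applied to follow-up
   totals of intervention participants only. Reported to the nearest
   euro; the unrounded value is carried internally.
2. **Marginal medication costs** — only medications *stopped* (present at
   baseline, not at follow-up) and *started* (the reverse) are costed,
   each as `ceil(horizon / dispensing_interval)` dispensings of
   (ingredient cost per interval + pharmacy dispensing fee). Stopped
   medications enter with a negative sign, so a participant whose
   deprescribing savings exceed other outlays has a negative total; the
   estimation stage must therefore tolerate negative outcomes. Ceiling
   division is used because a dispensing is indivisible; whether a trial
   would cost a partial final dispensing proportionally is not knowable
   from outside, so the convention is documented and the horizon
   configurable (the 3-month horizon is a standard sensitivity scenario).
   Excluded line classes (non-covered non-prescription items, non-drug
   products, hospital-only high-tech drugs) carry an `included` flag and
   contribute nothing.
3. **Primary/secondary-care utilisation** — counts of nine service items
   (five GP consultation types, practice-nurse consultations, outpatient
   visits, inpatient nights, emergency-department visits) priced by a
   unit-cost vector in a stated price year. Unit costs are *inputs* (a
   two-column delimited file); price-year adjustment is a single
   multiplicative index per scenario, not computed internally.

A missing component leaves the total missing; item-level missingness is
resolved by imputation, never by silent zero-filling.

### Utilities and QALYs

EQ-5D-5L responses locate a participant in one of 3,125 states; a value
set maps states to utility indices with 11111 anchored at 1. The value
set is data, not code: any complete state→score table or additive
per-dimension decrement table is accepted. The shipped `synthetic_value_set`
spans [−0.974, 1] — the published Irish index range — via plausible
convex decrement ladders; it is a synthetic stand-in for testing and
examples, not the national tariff.

QALYs gained over the window are the trapezoid
`h · (u_baseline + u_followup) / 2` (h = 0.5 years), so six-month QALYs
lie in [−0.487, 0.5] under the shipped range and the rule is exactly
linear in each utility.

**Decedents.** How the reference analysis valued QALYs for participants
who died is unreported, so the rule is configurable and logged per run:
`zero_from_death` (default) scores the follow-up assessment 0 and keeps
the full-horizon trapezoid (the death date is unknown); `midpoint`
assumes linear decline to death at mid-horizon (`h·u_baseline/4`);
`exclude` drops decedents from the QALY analysis.

### Multiple imputation

Item-level resource costs and EQ-5D-5L index scores are imputed
*independently* (single pass in a fixed variable order, not chained
equations), matching a design in which each item's imputation model is
fitted on its own complete cases. For each target: an OLS imputation
model on the complete cases produces predicted means for all rows; each
missing row borrows the observed value of one of the `knn = 5` complete
cases with nearest predicted mean (uniform draw among the pool; distance
ties broken by stable sort); the procedure repeats M = 10 times on
independent, name-keyed substreams, so one variable's missingness pattern
never perturbs another variable's draws — this is what makes cost-side
sensitivity scenarios leave the QALY side bit-for-bit unchanged.
EQ-5D-5L is imputed on the index-score scale (the scale analysed), not
the 5-digit state. Imputed totals are re-derived by summing imputed item
costs; observed cells are never altered, and every imputed value is an
observed donor value (so imputations respect the observed support).

Because the matching metric was an open choice, two variants ship:
`"bootstrap"` (default) refits the imputation model on a bootstrap
resample of the complete cases in each imputation, propagating model
uncertainty into the donor ranking; `"plain"` fixes the single
complete-case fit. Default predictors are age, sex, arm, baseline
medication count, private insurance, medical-card status, and the
practice identifier as fixed-effect indicators. Two caveats attach to
that last choice. First, the arm indicator is linearly spanned by the
practice indicators in a cluster-randomised design; the minimum-norm
least-squares fit absorbs the redundancy (predictions are unaffected) and
the event is logged. Second — a known finite-sample property worth
spelling out — when few outcomes are observed per cluster, the fitted
cluster effects are noisy, donor matching partially selects on that
noise, and imputed values regress toward the grand mean, attenuating the
arm contrast. The package's validation study of imputation therefore uses
the *congenial* individual-level predictor set (the default covariates
plus the baseline analogue of the target, without cluster indicators),
which the simulations in the test suite show to be unbiased under MAR;
analysts imputing many small clusters should consider the same.

Pooling follows Rubin's rules: pooled estimate = mean of the M estimates;
total variance `W + (1 + 1/M)·B`; degrees of freedom
`(M−1)(1 + W/((1+1/M)B))²` (infinite when B = 0, recovering the
complete-data analysis when nothing is missing). Inference on pooled
estimates uses the t distribution on those degrees of freedom.

### Estimation

Costs and QALYs are analysed with generalized estimating equations over
practice clusters: exchangeable working correlation, gamma variance /
identity link for costs (gaussian and log / power-1.5 links available as
scenarios), gaussian / identity for QALYs, covariates = treatment arm +
the baseline analogue of the outcome, cluster-robust (sandwich)
covariance. Adjusted per-arm means come from recycled predictions:
predict every participant under each arm assignment and average; under
the identity link the contrast equals the arm coefficient exactly, and
delta-method variances use the analytic gradient (identity) or central
finite differences (other links). 95% intervals are Wald on the robust
SE; small-sample sandwich corrections are off by default but switchable
(`bias_reduced_cov`).

Numerical choices: the gamma variance is evaluated as
`max(|μ|, 1e−6)²` so that negative totals and near-zero fitted means do
not break the estimating equations — required because deprescribing
savings genuinely produce negative totals. Estimating-equation updates
that oscillate below the convergence tolerance at the iteration cap are
accepted when the coefficients are finite; non-finite coefficients or
solver failures raise, and a failure on any imputed dataset reports the
imputation index. The quasi-likelihood criterion (QIC) is reported when
defined; it is undefined for gamma fits on negative outcomes and is then
omitted rather than fabricated.

### Net benefit, CEACs and dominance

Net benefit folds cost and effect into `nb = e·λ − c`; the intervention
is cost-effective at λ iff the incremental net benefit is positive. INB
is estimated by a gaussian/identity GEE on nb controlling for arm and
clustering, at the Irish reference thresholds €20,000 and €45,000 per
QALY by default; the CEAC grid spans €0–€100,000 in €10,000 steps plus
€45,000.

Three probabilistic methods:

* **Two-stage bootstrap** (default; respects clustering and the
  cost–effect correlation): stage 1 resamples clusters with replacement
  within each arm, preserving the arm's cluster count; stage 2 resamples
  participants with replacement within each drawn cluster to its original
  size, with drawn clusters relabelled as distinct. Naive two-stage
  resampling double-counts within-cluster variance (the variance of a
  drawn cluster's resampled mean is the between-cluster variance of
  cluster means *plus* the within-resampling variance), so a shrinkage
  correction deflates each cluster's outcome-mean deviation by
  `c = sqrt(max(0, 1 − v̄/S_b²))` per arm and outcome, making the
  resampled cluster-mean variance match the between-cluster variance;
  the naive scheme remains selectable (`shrinkage=False`). Each replicate
  refits the cost and QALY models and records the recycled-prediction
  contrasts (a no-refit variant that resamples participant-level outcomes
  and takes raw arm-mean differences is selectable); non-convergent
  replicates are redrawn and counted, with a warning past 5% of B.
  Replicates are allocated as evenly as possible across the M imputed
  datasets and the draws stacked rather than Rubin-pooled — probabilities
  are not normally distributed pooled quantities. The CEAC value at λ is
  the fraction of replicates with `ΔQ̂_b·λ − ΔĈ_b > 0`; at λ = 0 this is
  the fraction of cost-saving replicates and as λ → ∞ the fraction of
  QALY-gaining replicates. At B = 2000 the binomial standard error of any
  probability is at most 0.012.
* **Parametric**: Φ(INB/SE) from the net-benefit regression at each λ
  (0/1 by sign when SE = 0).
* **Monte Carlo**: normal draws around (ΔĈ, ΔQ̂) with their robust SEs,
  independent by default with an optional correlation input. On skewed,
  clustered data this method is expected to disagree with the other two;
  on gaussian data with a common estimand all three coincide, which the
  test suite verifies.

Dominance classification: ΔC < 0 and ΔQ > 0 → dominant; ΔC > 0 and
ΔQ < 0 → dominated; otherwise the ICER ΔC/ΔQ, reported as undefined when
ΔQ = 0.

### Sensitivity engine

Scenarios are declarative overrides on the base configuration: halve or
double the intervention cost, ±15% unit costs, 3-month medication
horizon, exclusion of components (e.g. stopped medications,
hospitalisation), alternative cost family/link, unadjusted or reduced
covariate sets, a post-pandemic-period covariate or subgroup, imputation
variants (M = 5, knn = 10, target subsets), and exclusion of
negative-total participants. The neutral scenario is a bitwise fixed
point of the base case. Only scenarios that change the imputation
machinery shift the run seed (by a stable per-name offset), so cost-side
overrides are attributable to the override itself: they cannot move the
QALY side, and the battery's ΔQ̂ column is constant across cost-only
rows. Per-scenario failures are isolated into an error column and the
battery continues.

## The synthetic-trial generator

The generator emulates the statistical structure of a practice-randomised
deprescribing trial in older multimorbid adults: by default 25 clusters
per arm of Poisson-sized ~8 participants (minimum 1); ages ~N(76.5, 6.8);
57% female; 90% medical-card and 35% private-insurance coverage; ≥15
baseline medications (rounded N(17.4, 3.5)); six-month utilisation cost
with mean €3,800 and gamma shape 0.3 (coefficient of variation ≈ 1.8)
dominated by inpatient nights; utilities with mean ≈ 0.48 and SD 0.37 on
[−0.974, 1]; intra-cluster correlation 0.05 on both scales; a 5.2% death
rate; 43% follow-up utility missingness and 12% per-item cost
missingness; and a 26% post-pandemic follow-up share.

Key constructions, chosen so the configured arm effects are *exact*
estimands:

* **Costs.** A latent per-period utilisation cost is gamma-distributed
  with multiplicative unit-mean log-normal cluster frailty (log-sd solved
  in closed form from the target ICC and gamma shape) and a shared
  individual frailty linking baseline and follow-up. The latent cost is
  split across the nine service items by fixed shares calibrated to the
  cost composition of a six-month period in this population, and
  converted to integer counts by randomised rounding
  (`floor(x) + Bernoulli(frac(x))`), which preserves the expected priced
  cost exactly. `true_delta_cost` shifts the intervention arm's follow-up
  latent mean additively; it is defined on *utilisation* cost, so the
  pipeline's total-cost estimand equals `true_delta_cost` plus the
  allocated intervention delivery cost. A `cost_distribution="gaussian"`
  variant (clipped at zero; negligible mass at the CVs used) supports
  normality-based method-agreement studies.
* **Utilities.** Truncated-normal draws on the value-set range whose
  *location is numerically calibrated* (vectorised bisection on the
  closed-form truncated mean) so the post-truncation mean equals the
  configured mean — an uncalibrated truncated draw would attenuate
  `true_delta_utility` by roughly 10% at the default SD, quietly biasing
  every downstream validation. Follow-up utility anchors on the
  individual's baseline deviation (correlation 0.5) and adds
  `true_delta_utility` in the intervention arm.
* **Medication change lines** (counts, ingredient costs, dispensing
  intervals, inclusion flags) are distributed identically in both arms,
  so the entire configured cost effect flows through the latent
  utilisation cost and the medication component only adds realistic
  noise — including naturally occurring negative totals.
* **Deaths** are arm-independent; a death sets follow-up utility to 0 and
  halves the expected follow-up utilisation, giving the decedent rules
  data to act on.
* **Missingness** masks follow-up utility and follow-up cost items with
  probability logistic in standardised age and baseline cost (weight
  `mar_covariate_weight`; 0 recovers MCAR), with the intercept calibrated
  per dataset so the marginal rate matches the configured rate. Masking
  never reads follow-up values: the mechanism is MAR given observed
  covariates, and the pre-masking copy is retained for oracle tests.

What the generator does *not* emulate: correlation between cost
components beyond the shared frailties (components are independent given
the latent cost), item-specific overdispersion patterns, informative
(MNAR) non-response, seasonal or calendar structure, and any arm
imbalance at baseline. Passing tests therefore demonstrate that the
pipeline's machinery is correct and calibrated under its stated
assumptions — not that any real trial's conclusions are reproduced, which
would require the original participant-level data.

## Validation-study designs used by the test suite

* **Parameter recovery**: 200 replicate complete-data trials of 50
  clusters per arm × ~8 participants, ΔC = −400 €, ΔQ = 0.014, ICC 0.05,
  zero intervention delivery cost (so the configured values are the exact
  truths), no deaths (a nonzero death rate would attenuate the utility
  estimand by the death rate). Checks: unbiasedness within 3 Monte-Carlo
  SEs and 95% interval coverage within [0.92, 0.98].
* **Imputation validity**: the same design with 40% MAR follow-up-utility
  non-response, PMM (M = 10, knn = 5) with the congenial predictor set
  discussed above; pooled estimates unbiased within 3 Monte-Carlo SEs and
  the Rubin total variance never below the within-imputation variance.
* **Method agreement**: one gaussian-cost trial at the same scale
  (gamma shape 4, no individual frailty), arm-only models so all three
  CEAC methods target the same marginal contrast; the three curves agree
  within ±0.03 at every grid point at B = 2000.

Problem sizes were chosen so the full suite runs comfortably on a single
CPU; the replication counts above set the Monte-Carlo resolution of each
check and are stated with the results they qualify.

## Known limitations

* No MNAR sensitivity models and no multilevel (random-effects)
  imputation; the cluster-as-fixed-effect imputation caveat above applies.
* No random-effects or Bayesian alternative to the GEE estimator.
* The |μ| guard for gamma variance on negative totals is an
  implementation convention; excluding negative totals is provided as a
  scenario instead of a resolution.
* No value-of-information analysis and no extrapolation beyond the trial
  horizon; six-month QALY differences in this population are inherently
  small relative to their uncertainty.
* The shipped value set and unit costs are synthetic stand-ins with
  realistic magnitudes; real analyses must supply their jurisdiction's
  tariff and unit-cost vector.
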