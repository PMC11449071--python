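# Methods

`frailtraj` implements a longitudinal claims-based frailty analysis for a
cohort of older women initiating adjuvant chemotherapy after early-stage
breast cancer surgery, compared with matched noncancer beneficiaries.
Because the administrative data such analyses run on (linked cancer
registry + Medicare claims) are restricted, every stage is developed and
validated against a synthetic claims generator whose latent structure
matches the analysis's assumptions.  This note documents the models, the
conventions, the generator, and what passing tests do and do not show.

## Date and window conventions

* **Ascertainment window.** All claims lookups use the half-open window
  `[anchor − L, anchor)` with `L = 180` days by default.  The anchor day
  itself is excluded so that same-day treatment claims cannot enter a
  baseline window.  Published descriptions of this design say only "claims
  during the 180 days prior to the timepoint"; the half-open choice is a
  convention of this package and is applied uniformly through a single
  function (`claims_core.in_window`).
* **Months.** A follow-up "month" is a 30-day block: 4 months = day 120,
  10 months = day 300, 12 months = day 360.  This matches the design's own
  equation of "6-month" with "180-day" windows.
* **Age.** Age at an anchor is `anchor_year − birth_year`; the data model
  carries no birth month.
* **Enrollment.** Continuous fee-for-service coverage of `[start, end]`
  tolerates no gap days by default (`gap_tolerance_days` is configurable
  for 1-day administrative artifacts); abutting spells merge.

## Frailty score

The frailty proxy is a logistic-index score: 20 binary claim-derived
indicators (17 deficit indicators such as wheelchairs, home oxygen or
heart failure, plus podiatric and rehabilitation services, and 2
protective screening indicators — cancer screening and lipid abnormality)
are combined with age and race terms in a linear predictor and mapped
through the inverse logit, giving a predicted probability of frailty in
(0, 1).  Indicators are binary (any mapped claim in the window), so the
score is invariant to claim duplication and ordering.

The published index's fitted coefficients are not reproduced here.  The
package ships a *synthetic default* coefficient set: deficit coefficients
in 0.3–1.0, screening coefficients −0.5/−0.6, age slope 0.025 per year
over 65, intercept −3.41.  Magnitudes were fixed once, jointly with the
generator's claim loadings, so that cohort-level mean scores fall in the
0.03–0.07 range typical of community-dwelling Medicare populations.  Any
published coefficient set can be supplied as YAML
(`FrailtyModel.from_yaml`).  The sensitivity variant removes the two
screening indicators by zeroing their coefficients (flags are still
extracted for prevalence reporting); the operation is idempotent and
suffixes the model id.

Monthly score series run from day 0 to day 360 in 30-day steps (13
anchors, day 0 included as the natural baseline; `include day 0` can be
dropped by passing a different anchor grid).  Anchors on or after the
death date, or after the end of the merged FFS spell containing the index
date, are omitted — missingness is therefore always a suffix.

## Cohorts

Eligibility for the chemotherapy cohort: age ≥ 65 at diagnosis, stage
I–III, primary surgery within [0, 90] days of diagnosis (closed interval:
"within 90 days" read inclusively), adjuvant chemotherapy within [0, 90]
days of surgery (chemotherapy start = index date), no neoadjuvant
chemotherapy, and continuous FFS enrollment from diagnosis to index or for
180 days pre-index, whichever is longer.  Each step's removals are logged
in an ordered exclusion ledger.

Comparators are matched exactly on (birth year, region), up to 5 per case,
uniformly at random *without* duplication within a match group and *with*
replacement across groups; they inherit the case's index date and must
satisfy the 180-day enrollment rule at it.  Cases with no eligible
comparator keep their row and are counted.  The comorbidity covariate is a
weighted condition sum over the 180-day window with cancer conditions
excluded; the weight table is a configurable synthetic default in the
spirit of the combined Charlson/Elixhauser score (including one negative
weight so the "<0" reporting bin is populated).  Flu vaccination in the
180 days pre-index serves as a health-seeking proxy.

## Weighting

* **SMR weights** standardize comparators to the chemo cohort: treated
  weight 1, comparator weight `ps/(1−ps)` from a logistic arm-membership
  model on age, race, region, comorbidity category and flu vaccination.
  Weights above the 99th percentile (comparator side) are capped by
  default; extrema before/after truncation are recorded.  Categorical
  levels with fewer than 5 members in either arm are merged into the
  reference before fitting — such cells quasi-separate the fit, and a
  stratum with no treated members cannot be standardized to the treated
  distribution by any weight.  Balance diagnostics (standardized mean
  differences, unweighted vs weighted) are reported on the modeled coding.
* **Attrition weights (IPAW).** Two discrete-time hazard (pooled logistic)
  models — one per cause, death and FFS disenrollment — are fit over the
  periods (T1,T2] and (T2,T3].  A person contributes a period only if
  observed at its start; the first event removes later contributions, and
  death takes precedence within a period.  The weight at timepoint k for a
  person still observed is the inverse product of the predicted
  cause-free probabilities over periods up to k; T1 weights are 1.
  Weights are unstabilized (no stabilization is described in the emulated
  design) and truncated at the 99th percentile by default.  Default
  covariates are age, flu vaccination, the time-varying comorbidity score
  and the frailty score at the period start; full race/region dummies are
  deliberately excluded from the default because rare attrition events
  quasi-separate sparse cells (the exact covariate list of the emulated
  analysis is only partially enumerated, so this list is a documented
  reconstruction).
* Death is treated as attrition to be upweighted (the emulated design's
  choice); censoring at death instead is a matter of dropping the death
  model's weights and is left to the caller.

## Benchmark marginal model

The three-timepoint panel (T1 = index, T2 = +120 d, T3 = +300 d) is fit by
GEE with mean model

    E[Y] = b0 + b1·chemo + b2·1[T2] + b3·1[T3] + b4·chemo·1[T2] + b5·chemo·1[T3],

gamma variance function, identity link, AR(1) working correlation over the
three occasions treated as equally spaced, observation weights equal to
SMR × IPAW, each cohort row its own cluster, and robust sandwich CIs
(whether the emulated analysis used model-based or robust intervals is
unstated; robust is the default here and recorded in the output).  The
CIs do not account for estimation of the weights — a known limitation.
Marginal arm×time means are linear combinations of the coefficients with
delta-method intervals.  A panel the model fits exactly (e.g. constant
outcome) is solved by least squares with zero-width intervals, since the
score equations degenerate.  Estimation is delegated to statsmodels; the
test suite holds an independent hand-rolled estimating-equation oracle
(IRLS with 1/μ² weights under working independence) against which point
estimates are checked.

## Trajectory clustering

Per-person monthly score series form an n × 13 matrix with NaN suffixes;
persons with fewer than 3 observed anchors are dropped.  Distances use
available-anchor rescaling,

    d²(a, b) = (T / T_obs) · Σ_{t observed in both} (a_t − b_t)²,  T = 13,

the common choice in longitudinal K-means practice (the emulated method
names the algorithm but not its missing-data metric).  Lloyd iterations
alternate nearest-center assignment with center updates by anchor-wise
*weighted* means (weights T/T_obs): the weighted mean is the exact
minimizer of the objective above, which makes the within-cluster sum
provably non-increasing per iteration; unweighted means can violate that
monotonicity under dropout.  Empty clusters are repaired by reseeding with
the farthest trajectory.  Initialization is greedy k-means++ under the
same metric (several distance-sampled candidates per seed, keeping the
potential minimizer); this is what makes 1%-mass clusters reliably
discoverable — plain random seeding almost never lands in them.  Runs are
restarted (default 20) and the best within-cluster sum kept;
fixed seeds make everything reproducible.

The number of clusters is selected over k = 2…8 by a Calinski–Harabasz
criterion, `C = [B/(k−1)]/[W/(n−k)]`, with both dispersions computed under
the missing-aware distance (the named "variant" criterion of the emulated
software is not specified; this reconstruction is configurable).  Soft
memberships use a Gaussian kernel with the pooled within-cluster variance
W/(n−k) as bandwidth — again a documented reconstruction, since the
original posterior formula is unstated — and the reported summary is the
mean assigned-cluster posterior.

Cluster centers are labelled by an explicit shape rule with baseline
b = center[0], peak p and end e: robust if p − b < 0.02; else resilient if
the decline recovers at least half of the rise (p − e ≥ 0.5·(p − b)); else
nonresilient.  Level tags cut the baseline at 0.05/0.15.  All three
constants are configurable and reported alongside results; the emulated
study labelled clusters by inspection.

## Nonresilience predictors

A logistic regression contrasts nonresilient cluster membership against
robust-or-resilient, with age centered at 65, race (reference White, the
two smallest groups collapsed into "Other"), region (ref West), stage
(ref I), surgery type (ref breast-conserving), grade (ref well
differentiated), comorbidity category (ref ≤0), flu vaccination, and the
20 baseline indicator flags — one joint model, as the emulated report's
single-column layout suggests.  Effects are odds ratios with Wald 95%
CIs.  Persons dropped from clustering have no label and are excluded.
Perfect separation raises an explicit error; the pipeline falls back to a
ridge-penalized fit (no CIs) when the ML fit separates, which happens at
moderate n because several indicator flags are rare.

## Synthetic generator

The generator emulates the study conditions, not the billing system:

* **Latent classes.** Chemo-arm persons belong to one of six latent
  trajectory classes mixed at (0.78, 0.15, 0.01, 0.04, 0.01, 0.01): one
  flat robust class, two rise-and-recover resilient classes (latent peak
  near month 2, matching an end-of-treatment score peak once the 180-day
  lookback smoothing is applied), and three monotonically worsening
  nonresilient classes.  A small person-level offset (SD 0.012) is added
  and curves are clipped to [0.004, 0.95].
* **Comparator pool.** Pool members carry a gamma-distributed latent base
  (shape 2, mean 0.058) plus an age-tied drift of +0.015 latent units per
  year, giving mean *scores* near 0.055 at matched ages with a ~+0.007
  rise over 12 months.  Pool size is 5× the chemo cohort, with birth years
  and regions resampled from the chemo distribution so exact matching has
  support.
* **Claims.** For each indicator, P(any claim in a 180-day window) =
  invlogit(a_j + b_j·latent), positive b for deficits and negative for
  screening; monthly Bernoulli draws use the consistent per-30-day-block
  probability 1 − (1 − p_window)^{1/6}.  In the chemo arm, screening-claim
  probabilities are multiplied by 0.35 (months 0–3) and 0.65 (months 4–6)
  for cancer screening (0.75/0.9 for lipid work), emulating deferral of
  routine care during treatment and its partial rebound.  Comorbidity
  condition claims, flu vaccinations, screening mammograms, surgery and
  chemotherapy-cycle claims are generated alongside.
* **Attrition.** Death and disenrollment are per-30-day-block logistic
  hazards in latent severity (death: intercept −7.35, slope 6, chemo-arm
  offset +1.0), calibrated to ≈2–3% chemo-arm and ≈1% comparator deaths
  within 10 months, with informativeness guaranteed by the positive slope.
  Claims stop at death/disenrollment; enrollment spells end accordingly.
* **Ground truth** (class labels, latent series, attrition dates) is
  emitted in a separate table that no analysis stage reads.
* Direct simulators bypass the claims layer for estimator validation:
  `generate_gee_scenario` draws gamma marginals with the benchmark mean
  structure and a Gaussian copula AR(1) dependence; ``generate_trajectory_mixture``
  draws score-space trajectories (class curve + anchor noise, default SD
  0.01 giving strong separation) with informative dropout.

**What the generator does not emulate:** real ICD/HCPCS coding, billing
artifacts, seasonal and geographic claim patterns, calendar trends in
practice, measurement correlation between indicators beyond the shared
latent, or treatment discontinuation.  Passing tests therefore demonstrate
that the estimators recover known structure under the stated assumptions,
not that the pipeline is robust to real-data pathologies.

## Problem sizes and numerical choices

Default simulated studies use 1,500–2,000 chemo cases with a 5× pool — the
size at which every stage's behavior is stable and a full run completes in
a few minutes on one core.  At this scale the end-to-end cluster selection
typically finds 2–4 clusters: claim-level Bernoulli noise in the scores
swamps the 1%-mass classes, which were resolvable in the emulated study
only because its cohort exceeded 20,000.  Cluster-count recovery is
therefore validated on the direct score-space mixture at its stated
separation, where selection of k = 6 with ARI ≥ 0.9 succeeds in ≈90% of
seeded runs.  Logistic fits use IRLS to tolerance 1e−12 (the saturated
SMR balance identity holds to 1e−10); separation is declared when the
linear predictor exceeds 30 in absolute value; GEE runs up to 100
iterations; K-means up to 200 Lloyd iterations with convergence on stable
assignments.
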