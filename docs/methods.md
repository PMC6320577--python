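# Methods

## The score

The Erlangen Score condenses the CSF Alzheimer profile into an ordinal
scale.  Two marker groups reflect the two pathophysiologic processes:
amyloidosis (Aβ1–42 concentration and the Aβ42/40 ratio, pathologic when
*decreased*) and neurodegeneration (total Tau and pTau181, pathologic when
*increased*).  Each marker is compared with a laboratory-specific reference
value; a result that is pathologic by direction but within a relative band
of the cutoff (default 10 %) counts as a *border* result.  Severities are
0/1/2 per marker (normal/border/pathologic), a group's severity is the
maximum over its available markers ("and/or" logic — one evidently altered
marker suffices), and the total score is the sum of the two group
severities.  Scores 0–1 are reported as "neurochemically improbable AD",
2–3 as "possible", 4 as "probable".

Two conventions had to be fixed that the verbal rules leave open:

* **Cutoff boundary.** A value exactly at the cutoff is *normal*; the
  border zone is strictly beyond the cutoff, up to and including the band
  edge (0.9× for decreasing markers, 1.1× for increasing ones); pathologic
  is strictly beyond the band.  Pathology begins beyond the reference
  value, and fixed edges make the classifier exactly testable.
* **Band geometry.** The band is multiplicative ("10 % decrease/increase"),
  which makes the classification invariant under a common rescaling of
  value and cutoff — reference values are centre-specific, so this scale
  freedom is the natural choice.

Missing markers: a group is scored from whatever markers are available
(minimum one per group; otherwise no score is emitted and the record is
flagged).  A measured Aβ42/40 ratio takes precedence over the quotient of
the measured Aβ species.  Inputs are never rounded; comparisons are at full
floating precision.

## Synthetic cohorts

The generator emulates a four-group memory-clinic cohort (neurologic
controls, stable MCI, MCI-to-ADD progressors, ADD patients; default sizes
66/74/70/168) whose biomarker distributions are known only through
median/IQR summaries.

* **Marginals.** Each biomarker is log-normal with μ = ln(median) and
  σ = ln(q75/q25)/(2·z₀.₇₅), z₀.₇₅ ≈ 0.6745 — the simplest strictly
  positive family that matches a printed median/IQR pair.  Age and MMSE
  are truncated normals (age ≥ 40; MMSE rounded into [0, 30]); sex and
  APOE ε4 carriage are Bernoulli with the published group fractions.
* **Dependence.** Markers are joined by a Gaussian copula.  The published
  summaries carry no correlation information, so defaults are field-typical
  round numbers: ρ(Tau, pTau181) = 0.8, ρ(Aβ42, Aβ40) = 0.6, others 0; all
  configurable.
* **Amyloid consistency.** Aβ42 and Aβ40 are sampled jointly and the ratio
  is their literal quotient; Aβ40 is then rescaled by a group constant so
  the ratio's median equals its published value.  The three published
  amyloid medians are not mutually consistent (e.g. 852.9/8833 ≈ 0.097,
  printed ratio 0.100), so all three cannot be matched simultaneously; the
  generator pins the two quantities that enter the score (Aβ42 and the
  ratio), leaving the sampled Aβ40 median at median(Aβ42)/median(ratio),
  up to ≈ 7 % away from its printed value depending on the group.
* **Progression.** MCI subjects progress with piecewise-constant hazard
  λ(t) = baseline · HR(category, t) driven by their *scored* three-level
  category.  Defaults: baseline 0.04/yr — chosen so the improbable
  category's cumulative incidence by year 4 is ≈ 15 %, matching the
  reported behaviour of biomarker-negative MCI — with hazard ratios 7.67
  (possible, first 3 years), 1.04 (possible, after 3 years) and 12.0
  (probable, time-constant): exactly the effect structure the Extended Cox
  Model estimates, so parameter recovery is a meaningful end-to-end check.
  Event times come from the closed-form inverse of the piecewise
  cumulative hazard.  Administrative censoring is Uniform(2, 12) years
  (follow-up of at least two years, maxima 10–16); an event at exactly the
  censoring time counts as an event.  Progressors are relabelled "MCI-AD",
  the rest "MCI-Stable", mirroring how such cohorts are defined post hoc.

All draws flow through a single `numpy.random.Generator`; a configuration
plus seed reproduces the cohort bit for bit.

What the generator does **not** emulate: real dropout patterns (censoring
is uniform, not the staggered accrual visible in clinical risk tables),
within-subject biomarker drift (baseline values are assumed constant over
follow-up, as in the analysis model), assay noise structure, and any
correlation between demographics and biomarkers.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data features.

`erlangen.datasets.reconstruct_reference_cohort()` is a synthetic stand-in
built from the published category *counts*: each reconstructed subject gets
a representative panel for their category, demographics are filled with
neutral constants, and MCI event times are drawn (fixed internal seed) from
the default hazard model conditioned on progression within 8 years.  Only
its category distribution is faithful to the source; everything else is a
stand-in that lets the full pipeline run end to end.

## Survival stack

Implemented directly on counting-process data, with lifelines used only as
an independent oracle in the tests.

* **Estimators.** Kaplan–Meier S(t) = Π(1 − dᵢ/nᵢ) and Nelson–Aalen
  H(t) = Σ dᵢ/nᵢ over distinct event times, with risk tables on a
  configurable interval grid (default 2 years).
* **Weighted log-rank.** Pooled over event times with hypergeometric
  variance; weights 1 (log-rank) or n-at-risk (Gehan–Breslow–Wilcoxon);
  the trend test contrasts the per-group observed-minus-expected vector
  with ordinal scores (default 0, 1, …) on the full covariance, df = 1.
* **Episode splitting.** Follow-up is split at 3 years (configurable).
  The "possible" indicator becomes possible_early = possible·1(t ≤ 3) and
  possible_late = possible·1(t > 3); "probable" stays time-constant.  An
  event at exactly the split belongs to the early interval ("less or equal
  than 3 years").  Splitting conserves exposure and events exactly; rows
  use the (start, stop] risk-set convention (at risk at t iff
  start < t ≤ stop).
* **Cox fitting.** Newton–Raphson with step-halving on the partial
  likelihood; convergence when |Δ log-lik| < 1e-9 or ‖score‖ < 1e-9, at
  most 100 iterations.  Breslow tie handling is the default (matching the
  default of the commercial survival software these analyses are usually
  run in), Efron is available.  Risk-set sums are computed with suffix
  cumulative sums over stop- and start-sorted episodes, which keeps a
  5 000-subject ECM fit under 0.1 s.  Standard errors come from the inverse
  observed information; CIs are Wald on the log scale.  Collinear
  covariates raise a singular-information error; a monotone partial
  likelihood (complete separation — a coefficient drifting beyond ±15
  while the likelihood plateaus, or past ±30 during iteration) raises an
  explicit separation error rather than reporting a meaningless "infinite"
  hazard ratio.
* **Proportionality.** Grambsch–Therneau test on scaled Schoenfeld
  residuals with the identity time transform by default (again the named
  software's default; a KM transform is available): per-covariate df = 1
  chi-squares and a global test.  Validated against lifelines'
  `proportional_hazard_test` with identity transform.

## Cohort statistics

* **Kruskal–Wallis** on the ordinal contingency table via mid-ranks with
  tie correction C = 1 − Σ(t³−t)/(N³−N); algebraically identical to
  ranking the expanded per-subject vector (the test suite asserts equality
  with scipy's `kruskal` to 1e-10).  p from the chi-square approximation.
* **Dunn's pairwise contrasts** with the tie-corrected rank variance and
  Bonferroni correction over all k(k−1)/2 pairs.
* **Diagnostic accuracy** uses the asymmetric operating points at which
  such scores are reported clinically: sensitivity counts diseased
  subjects *not* scored improbable (ES ≥ 2 is a positive), while
  specificity counts controls *not* scored probable (only ES = 4
  misclassifies a control).  Only this pair of definitions reproduces the
  published 95 % / 98.5 % from the published table.
* **Landmark logistic models** ("progressed within h years", h = 3 and 5
  by default): subjects censored before the horizon without an event carry
  no landmark information and are excluded (this matches the published
  model sizes being below the full MCI count); a flag can instead count
  them as non-progressors.  Fits use statsmodels' IRLS (tolerance 1e-10,
  ≤ 50 iterations); the three-level category enters as two indicators
  against the improbable reference; Wald CIs on the log-odds scale.
* **Fast/slow contrasts.** Fast progressors develop dementia within 3
  years; slow progressors are dementia-free beyond 3 years; others are
  excluded.  An OLS model with cell-means coding of category × speed plus
  centred covariates (age, sex, MMSE) yields population-averaged cell
  means at the covariate means with 95 % CIs and per-category fast-vs-slow
  Wald contrasts.  A category with an empty stratum gets a NaN contrast,
  reported rather than raised.

## Numerical and design choices

* Default t test is Student's pooled-variance (Welch optional); two
  zero-variance samples with equal means give t = 0, p = 1 by convention.
* Percentages are rounded to one decimal for display; the JSON statistics
  bundle keeps full precision.  The analysis pipeline contains no random
  element, so identical inputs give byte-identical output.
* Simulation sizes used by the test suite and the acceptance script are a
  compromise between Monte-Carlo error and turnaround: marginal
  calibration at n = 10⁵ (median tolerance 2 %), ECM recovery at n = 5 000
  MCI subjects over 10–20 seeds (mean log-HR within 3 Monte-Carlo SEs of
  truth), Schoenfeld power at n = 2 000 over 200 replicates and type-I
  error at n = 150 over 500 replicates, log-rank type-I error at
  n = 50/group over 1 000 replicates.

## Known limitations

* The Dunn contrast between the control and stable-MCI groups on the
  three-category table has a Bonferroni-adjusted p of 0.009 — clearly
  significant, but not below the 0.005 reported for the five-category
  analysis, whose full count table is not public.
* Exact hazard ratios and confidence intervals of the original
  patient-level analyses are not reproducible without the (non-deposited)
  cohort; the package instead proves parameter *recovery* on synthetic
  cohorts with the same effect structure.
* No competing-risk handling (non-AD dementias are assumed excluded by
  design), no frailty/stratified/penalised Cox, no left truncation beyond
  what episode splitting requires, and no ROC machinery beyond the single
  published operating point.
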