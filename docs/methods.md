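# Methods

This note documents the statistical model behind `rdscompare`, the choices
made where the methodology leaves room, and what the synthetic generator
does and does not emulate.

## Recruitment forests and the analysis set

RDS data arrive as a participant table with recruiter links. The links must
form a forest: in-degree ≤ 1 (one coupon per recruit), no cycles, every
participant reachable from exactly one seed. Waves are graph distance from
the seed (seeds are wave 0, their recruits wave 1). Design choices:

* **Incomplete questionnaires.** Complete-case analysis is mandatory — the
  inverse-degree weights need the reported network size, which only
  completed questionnaires provide. An incomplete participant *with*
  recruits is kept as a structural node (recruitment happened regardless of
  completion, so recruits keep their true wave) and removed by the
  completeness filter; an incomplete seed *without* recruits never entered
  the process and is dropped at construction.
* **Analysis-set filter.** Default `min_wave=2`: seeds are a convenience
  sample and wave 1 still carries their composition; the equilibrium
  diagnostic typically justifies discarding exactly those. After the
  wave/completeness exclusions, a chain contributing a single participant
  is removed entirely — the chain-clustered variance needs ≥ 2
  observations per retained cluster. The filter is deterministic and
  idempotent by construction.
* **Coupon violations** (> 3 recruits) warn rather than fail, because field
  data contain them; `strict=True` upgrades them to errors.

## Equilibrium of the recruitment chain

Transition probabilities are estimated from recruiter→recruit pairs per
attribute (pairs with a missing value on either end are dropped and
tallied). The stationary vector solves the linear system `Eᵀ(S − I) = 0`
with `ΣE = 1`; power iteration is kept as an independent cross-check route
(the two agree to < 1e-8 over random irreducible matrices in the test
suite). Reducible or periodic chains raise an error rather than returning
an arbitrary fixed point; rows with no observed recruiters are never
imputed — if the stationary computation needs them, that is an error too.
`waves_to_equilibrium` iterates the start composition and reports the first
wave within `tolerance` (default 0.02, the conventional 2% band) of the
stationary vector in max-abs distance. The start composition defaults to
the seeds' own attribute distribution and is configurable to wave 1. Which
attribute "declares" equilibrium is left to the analyst; the pipeline
reports all of them.

## Estimation

* **Unweighted**: exact Clopper–Pearson intervals in Beta-quantile form
  (lower = Beta(x, n−x+1) quantile at α/2, upper = Beta(x+1, n−x) at
  1−α/2), closed at the boundaries. The construction guarantees
  at-least-nominal coverage; at n = 49 the true coverage over
  p ∈ {0.05…0.95} is 95.4–98.9%.
* **Weighted**: the inverse-reported-degree prevalence extended to
  multi-category variables (weights wᵢ ∝ 1/dᵢ normalised to sum 1; the
  label in outputs is `rds_weighted`). This is the documented estimator
  the package stands behind; weighted columns are validated by the
  simulation properties below, never by numeric replay of any external
  table. Degrees are used raw; a cap parameter exists but is off by
  default since degree trimming is not part of the design. When all degrees are
  equal the estimator returns the exact unweighted proportion (the degrees
  cancel algebraically; the implementation short-circuits so the identity
  holds bitwise).
* **Variance**: Taylor linearisation of the ratio estimator with
  with-replacement clustering at chain level,
  `V = m/(m−1) Σ_c U_c²` over cluster totals of uᵢ = wᵢ(yᵢ − p̂).
  Intervals are symmetric on the logit scale and back-transformed; the
  published weighted intervals' construction is unstated, and the logit
  scale was chosen for its boundary-respecting behaviour. Degenerate
  categories (p̂ ∈ {0, 1} or zero variance) collapse to point intervals.
* **Continuous variables**: Hájek weighted mean with the same linearised
  clustered SE.

## Tests

* Pearson chi-square is computed from first principles (needed so the
  corrected statistic can reproduce it bitwise at d̂ = 1); scipy is the
  oracle in tests.
* **Rao–Scott**: the phrase "continuity-corrected Rao–Scott chi-square"
  conflates two named adjustments, so both are explicit and recorded in
  the result: first-order design-effect scaling (statistic / d̂, df
  unchanged) and an optional Yates-style |O−E|−½ adjustment on 2×2
  tables. d̂ is the mean over non-degenerate categories of the ratio of the
  chain-clustered variance to p(1−p)/(n−1) — the (n−1) denominator makes
  a self-representing design (equal weights, unit clusters) give exactly
  d̂ = 1.
* **t-test** defaults to Welch/Satterthwaite; a pooled option is retained
  since the source analysis does not specify.
* **Negative binomial (NB2)** regression is fitted in-package: Fisher
  scoring with step-halving for the coefficients alternating with a
  bounded 1-D golden-section update of log-dispersion, stopping when the
  log-likelihood change is < 1e-8 (cap 200 iterations). Step-halving makes
  the likelihood trace monotone, which the test suite asserts; statsmodels'
  NB2 fit is the independent cross-check. SEs come from the expected
  information at the optimum; the Wald p-value is reported.
* Significance flags use α = 0.05 with no multiple-testing adjustment
  (noted in the report provenance block).

## Synthetic studies

The generator emulates the *selection mechanisms* the analysis must cope
with, not any real population:

* **Attributes** are drawn from a multinomial logit on a latent standard
  normal "integration" score with evenly spaced category scores; intercepts
  are calibrated by Gauss–Hermite quadrature so the realised marginals
  match the configured prevalences regardless of the loading. This gives
  correlated attributes (citizenship, age, education all load on the same
  score) with controlled marginals.
* **Network**: lognormal degrees (default mean-log 2.0, sd-log 0.9, min 1 —
  an assumption, not an estimate; the real degree distribution is
  uncharacterised), paired by biased stub matching: a stub insists on a
  same-category partner with the attribute's homophily probability
  (attributes trigger sequentially), otherwise matches uniformly.
  Self-loops and multi-edges are rejected; leftover stubs are dropped and
  isolates reattached so every member has degree ≥ 1. Reported network
  size equals true degree by default, with an optional multiplicative
  lognormal misreporting knob (inaccurate degree reports are a known RDS
  weakness).
* **Registry arm**: coverage is logistic in the integration score
  (undercoverage of the least integrated), a fixed invalid-address
  fraction, and logistic nonresponse in the score and any configured
  attribute loadings. The `munich2017` preset calibrates the response
  intercept so the covered frame responds at ~13%.
* **RDS arm**: seeds drawn with probability ∝ degree^bias (degree-biased
  convenience selection), 3 coupons each, independent acceptance per
  coupon, breadth-first without re-recruitment, stopping at the completed
  target. The preset enters 17 seeds of which one never participates,
  matching the scenario's topline counts (400 drawn / ~26 invalid / 195
  RDS completes incl. 16 seeds).

What passing tests on this generator show: the pipeline's filters,
weights, variances and corrections behave correctly under degree-biased
inclusion, homophily-induced clustering and attribute-dependent
nonresponse. What they do not show: anything about questionnaire
measurement, household or spatial structure, seasonal recruitment
dynamics, or the actual magnitudes in any real population — and the
generator does not attempt to reproduce published *weighted* estimates or
p-values, which depend on undeposited microdata.

## Numerical and scale choices

* Problem sizes: estimator-bias experiments use a 3,000-node network with
  200 random-walk replicates of n = 500; end-to-end recovery uses a
  6,000-node network with 200 RDS replicates of target 500; interval
  coverage uses 10,000 binomial replicates per grid point. These sizes put
  Monte-Carlo error well below the asserted tolerances (e.g. ±2 points for
  estimator bias) while keeping the default suite fast.
* Coverage checks compare empirical coverage against the nominal level
  minus three Monte-Carlo standard errors of the check itself
  (≈ 0.65 points at 10,000 replicates); the underlying construction is
  exact, the allowance is purely the simulation's own noise.
* Percent rendering rounds half-up to one decimal, matching conventional
  table formatting; full precision is kept internally and comparisons in
  tests use ±0.05 points (printed precision).
* Determinism: one `SeedSequence` per study spawns independent substreams
  for population, network, degree reporting, registry and RDS stages, so
  identical config + seed gives byte-identical tables.

## Known limitations

* The inverse-degree weighted estimator assumes with-replacement
  random-walk sampling at stationarity; real coupon-limited, without-
  replacement recruitment violates this, and the simulation checks bound
  the resulting bias (≤ 3 points in the tested scenarios) rather than
  eliminate it.
* The first-order Rao–Scott correction scales by the mean design effect
  only; no second-order (Satterthwaite) df adjustment is implemented.
* Single-attribute equilibrium only; joint equilibrium across attributes
  is out of scope, as are RDS-I group-ratio and successive-sampling
  estimators.
* A chain that dies out before wave 2 contributes nothing to the analysis
  set; with few seeds the weighted variance can rest on very few clusters,
  and the pipeline errors rather than silently under-covering when fewer
  than two chains remain.
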