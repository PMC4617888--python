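# Methods

## Model

Each person-day at risk in a retrospective mortality survey is treated as
an independent Bernoulli trial with death probability `p`. A survey
reporting `d` deaths over `T` person-days therefore contributes a
binomial likelihood, and a Beta(α, β) prior on `p` yields the conjugate
posterior Beta(α + d, β + T − d). Fractional person-days are accepted —
the update formulas extend continuously — which matters when person-time
is estimated as mid-period population × recall days.

All distribution mathematics runs on the probability scale; every
interface reports `r = 10,000 p` in deaths/10,000/day, the scale of
Sphere thresholds and SMART survey reports. The approximation
`Var ≈ T p (1 − p)` for the total death count ignores within-household
correlation and attrition during the recall window; at rates of a few
per 10,000/day both effects are second-order.

The model assumes `d` and `T` are exact aggregates of a simple random
sample. Cluster designs enter only through the design effect attached to
classical Wald intervals and through the simulator; the Bayesian update
itself does not discount person-time for clustering. For strongly
clustered surveys the posterior is therefore somewhat overconfident —
a known limitation shared by any aggregate-count conjugate analysis.

## Prior elicitation

A prior is specified by two interpretable constraints in rate units: the
mean `m` and one percentile (`level q`, value `x_q`). The mean constraint
eliminates one shape analytically, `β = α (1 − m/10⁴)/(m/10⁴)`, leaving a
one-dimensional root problem for α: `F_Beta(x_q/10⁴; α, β(α)) = q`.

The solver searches `log α ∈ [−10, 20]` (α from e⁻¹⁰ to e²⁰ — the
skeptical prior's effective prior sample size α + β reaches tens of
thousands of person-days, so α spans orders of magnitude). For an upper
percentile (q > 0.5) the CDF residual is **not** monotone over that
bracket: it starts near `1 − m − q` at tiny α (where the beta with a
fixed mean degenerates into a two-point spike at 0 and 1), dips as the
density spreads, and rises back to `1 − q` as α → ∞ and the prior
concentrates at the mean. Two roots can exist; the degenerate small-α
root is never the intended prior. The solver first locates the residual's
minimum (bounded scalar minimisation), declares the spec infeasible if
the minimum stays positive — a beta with a small fixed mean cannot push
an upper percentile much beyond ~2–3× the mean — and otherwise runs
Brent's method on the increasing branch, where the CDF is strictly
increasing in α and the root is unique. For a lower percentile the
residual is monotone and Brent runs on the full bracket. The elicited
prior is verified to reproduce both constraints to 1e-6 relative
tolerance before it is returned; `quantile_level = 0.5` is rejected
rather than special-cased (mean ≠ median for skewed betas).

## Highest-density interval

The 95% HDI minimises `Q(w + 0.95) − Q(w)` over the lower-tail mass
`w ∈ [0, 0.05]`, with `Q` the beta quantile function, using bounded
scalar minimisation (xatol 1e-10). This is exact for unimodal densities
and free of sampling noise; at the optimum the density heights at the two
endpoints coincide. Monotone-decreasing densities (α ≤ 1) anchor the
interval at 0, monotone-increasing ones (β ≤ 1) at 1, and bathtub shapes
take the narrower of the two boundary-anchored candidates.

## Exceedance and decisions

The probability of exceeding a threshold τ is the upper beta tail
`P(r > τ) = 1 − F_Beta(τ/10⁴; α′, β′)`; strict vs non-strict is
immaterial for a continuous posterior. The embedded baseline table stores
the *printed* Sphere values; emergency thresholds are operationally twice
the baseline rounded (half-up) to one decimal, and the table lookup — not
re-derivation — is authoritative in classifications. One table cell
(least-developed countries, under-five: printed threshold 1.7 vs doubled
baseline 1.6) deviates from the doubling rule; `doubling_rule_mismatches`
reports it, and the printed value is used. Classification ties go upward
(a rate exactly at threshold is an emergency, exactly at baseline is
elevated) — the cautious reading for humanitarian response. The default
evidence level for the trigger rule is 0.95 and is configurable.

## Worked-example fixtures

The two bundled examples reconstruct published survey summaries (Yida,
South Sudan 2012, under-five; Duhok, Iraq 2014, under-five and
all-ages). The original microdata are not public, so the `(d, T)` pairs
in `synthetic_examples.py` are synthetic stand-ins found by searching
integer death counts and person-day totals for the pair whose conjugate
posterior best reproduces the published summaries under the
exactly-elicited prior. For Duhok, `d = 4, T = 87,690` reproduces the
published crude rate (0.46), posterior mean (0.55) and exceedance
probability (56.9%) simultaneously at their printed precision. For Yida
no `(d, T)` reproduces all published values at once — the published
posterior summaries imply an effective prior (mean ≈ 1.11, 95th
percentile ≈ 2.15) slightly off its own stated constraints (1.07, 2.1),
presumably a loosely-converged optimiser in the original analysis — so
the chosen `d = 5, T = 12,025` favours the posterior mean (1.85) and
exceedance (30.9%); the HDI upper bound then computes 3.09 vs the
published 3.08, and the crude rate 4.16 vs the published, differently
adjusted, 3.98. The fixtures are fit for demonstrating the method, not
for re-auditing the original surveys.

## Synthetic surveys

`simulate_survey` emulates the aggregate output of a cluster mortality
survey. `T = n_individuals × recall_days` person-days are split evenly
across `C` clusters; cluster `c` draws deaths binomially with daily
probability `p_c = p ε_c`, where the `ε_c` are gamma with mean 1 and
variance `v`. With equal cluster sizes `t = T/C`,

    Var(d) = T p + t T p² v   ⇒   deff = 1 + t p v
    ⇒   v = (deff − 1) / (t p),

so the gamma shape `1/v` calibrates the between-cluster heterogeneity to
a requested design effect. Deaths retain full exposure (no attrition
within the recall window). One integer seed drives a root
`SeedSequence`; replicates use spawned substreams, so experiments are
reproducible end to end and independent of replicate order.

What the generator does *not* emulate: household rosters, migration in
and out of the population, age structure, violence-driven overdispersion
beyond the gamma mixing, and non-response. Passing coverage/power tests
therefore validate the inference machinery under the stated sampling
model, not the field realism of any particular survey.

## Test conditions and numerical choices

- Coverage calibration uses prior-matched truth (each replicate's `p`
  drawn from the prior), 2,000 replicates, 500 individuals × 90 days —
  a typical mid-size camp survey — and asserts nominal 95% HDI coverage
  within 3 Monte-Carlo standard errors.
- The data-dominance check uses `d = 1,000` deaths over `T = 10⁷`
  person-days (observed rate 1.0 deaths/10,000/day, between the two
  example priors' means): both the skeptical and the high-mortality
  prior leave the posterior mean within 0.01 of the observed rate. The
  observed rate is chosen between the prior means so the check measures
  exposure-driven dominance rather than the sheer distance of an extreme
  rate from a heavy prior.
- Grid-posterior oracles truncate the uniform probability grid just
  beyond the posterior's 1 − 1e-12 quantile and renormalise, keeping
  trapezoidal quadrature accurate to 1e-5 relative on means with
  ~4 × 10⁵ points.
- Monte-Carlo oracles (10⁶ beta draws) compare within 3 binomial
  standard errors; design-effect calibration compares batch-mean
  variance ratios within 4 batch standard errors at 2,000 replicates.
- Display rounding is decimal half-up (2 decimals for rates, 1 for
  percentages), matching printed humanitarian tables; internal values
  are never rounded.
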