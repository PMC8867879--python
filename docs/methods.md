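# Methods

## The problem being simulated

Lead time is the interval between detection of a cancer by screening and
the moment it would have been diagnosed symptomatically.  Because survival
metrics start their clock at diagnosis, moving diagnosis earlier inflates
survival-from-diagnosis even when the date of death is untouched.  The
package isolates this artefact: it builds a counterfactual world in which
screening changes *only* the diagnosis date, then measures how much the
standard prognosis metrics move.

Three metrics are tracked, all externally age-standardised over the
diagnosed cohort:

- 10-year relative survival, `R(10)`;
- loss in life expectancy,
  `LLE = ∫₀^tmax S*(t) dt − ∫₀^tmax S*(t) R(t) dt`;
- proportion of life lost, `PLL = LLE / ∫₀^tmax S*(t) dt`,

where `S*` is the expected (cancer-free) survival from the life table and
`R` the model-based relative survival, both extrapolated to `tmax`.

## Relative-survival framework

All-cause mortality of a patient is decomposed as
`h(t|Z) = h*(t|Z₁) + λ(t|Z₂)`: a known expected rate `h*` looked up in a
life table stratified by sex, attained age and calendar year, plus an
excess (cancer-related) rate `λ`.  On the survival scale
`S(t) = S*(t)·R(t)`.  Since `h*` is treated as known, the log-likelihood of
an administratively censored record `(tᵢ, dᵢ)` reduces to
`dᵢ·log(h*(exit) + λ(tᵢ)) − Λ(tᵢ)` up to a constant, which is what the
fitter maximises.

The excess hazard is modelled flexibly (Royston–Parmar style) through the
log cumulative excess hazard:

```
ln Λ(t | age) = s₀(ln t | γ, k₀) + α·age + age·s₁(ln t | δ, k₁)
```

with `s₀`, `s₁` restricted cubic splines of log time (piecewise cubic,
C², linear beyond the boundary knots; df = knots − 1).  The fitted
configuration uses df 3 for the baseline and df 3 for the time-dependent
age effect.  Setting df 1 and no time-dependence recovers a Weibull, which
is exploited throughout the test suite as a closed-form oracle.

Numerical choices:

- **Knots** at the min/max (boundary) and 33rd/67th centiles (internal) of
  the log event times — the conventional default when only the df is
  prescribed.  Both knot vectors are overridable.
- **Optimisation**: analytic gradient, BFGS, columns of the design scaled
  to unit maximum for conditioning, started from a Weibull (df-1) fit that
  is itself started at the exponential-rate estimate.  A quadratic penalty
  keeps the slope of the log cumulative hazard positive wherever the
  optimiser wanders; at a valid optimum the penalty is inactive.
  Non-convergence (gradient norm not small) raises rather than returning a
  silently bad fit.
- **Zero follow-up times** are floored at one day (1/365.25 years) because
  the model lives on log time.
- The **age covariate is centred** internally and the centring folded back
  exactly into the reported coefficients, so `alpha` is per year of age.

## Loss in life expectancy

`LLE` and the expectation in `PLL`'s denominator are computed by composite
Gauss–Legendre quadrature (8 nodes per panel by default) on panels aligned
with attained-age year boundaries, where the life-table hazard steps; the
integrands are smooth inside each panel.  Doubling the node count moves the
result by far less than 1e-6 years in the tested configurations.  `tmax`
defaults to `100 − age at diagnosis`, i.e. extrapolation ends at the
100-year cap where death is certain; this makes `LLE` the full remaining
lifetime contrast.  Expected survival `S*` treats rates as piecewise
constant on one-year intervals of attained age and calendar year
simultaneously, carrying the last tabulated calendar year forward when the
horizon outruns the table.

## External standardisation

Marginal estimates average individual predictions.  With ICSS weights the
average is `(1/N) Σ wᵢ·vᵢ` with `wᵢ = wˢᵢ / aᵢ`, the ratio of the reference
proportion of individual *i*'s age group (7/12/23/29/29% for ≤44, 45–54,
55–64, 65–74, ≥75) to its sample proportion.  A sample age group that is
empty while carrying positive reference weight is an error, not a silent
renormalisation; at desk scale this can occasionally abort a replicate,
which is then skipped and logged.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the Swedish continuous
tumour-growth model family: one tumour at most per woman, onset from
age-specific yearly probabilities, exponential volume growth
`V(t) = V₀·e^{t/τ}` with `τ ~ Gamma(shape, scale)` per woman, symptomatic
detection with hazard `η·V(t)` (closed-form inversion
`t = τ·log1p(E/(η V₀ τ))`), and death as the minimum of a generating-FPM
cancer death (clock at the latent symptomatic age) and life-table
other-cause death.  The published studies estimated their onset
probabilities, growth/detection parameters and generating-model
coefficients from Swedish registry data; those estimates are not printed in
any source available here, so the shipped defaults are **stand-ins chosen
once** to qualitatively match the documented cohort shape (median
symptomatic diagnosis age ≈ 62 with quartiles ≈ 50/73, most tumours below
32.5 mm, ≈ 51% 10-year net survival at age 62, ≈ 3,000 diagnoses per
replicate at full scale) and then frozen:

| parameter | default | meaning |
|---|---|---|
| onset probability | `0.0020·logistic((age−32)/6)`, 0 below age 20 | per-year onset risk |
| `d0` | 0.5 mm | diameter at onset (cell-cluster scale) |
| `τ` | Gamma(2, 0.5) years | volume e-folding time |
| `η` | 2.6e-4 /mm³/year | symptomatic-detection intensity |
| generating knots | t = 0.1, 1, 3, 12 y | baseline spline (log-time) |
| generating `γ` | (−3.3750, 0.7896, −0.0731, 0.1090) | net survival 0.88/0.72/0.63/0.51 at t = 1/3/5/10, age 62 |
| generating `α` | 0.02 /year | log excess-hazard ratio per year of age |
| life table | Gompertz–Makeham, a=3e-5, b=0.095, c=6e-4, drift 0.998/yr | female expected mortality |

Consequences: qualitative findings (signs and orderings of the bias, the
rough size of lead times) are meaningful; exact published magnitudes are
*monitored, not asserted*, and the test suite deliberately checks orderings
and signs at desk scale rather than point values.  Real-data features the
generator does not carry: in-situ/indolent tumours (all simulated tumours
eventually surface, so classical overdiagnosis is limited to deaths
intervening first), mammographic-density-dependent sensitivity, calendar
trends in the excess hazard, multiple primaries, and migration/coverage
artefacts of real registries.

## Scenario layering and randomness

Each replicate spawns independent substreams (via `SeedSequence`) for
onset, growth, detection, other-cause death, cancer death, attendance and
screen-detection uniforms.  The detection-uniform matrix is keyed by
(woman, visit) and the imperfect-attendance matrix by woman, both drawn
once per replicate and reused across all screening scenarios, so scenarios
differ only through the sensitivity curve and attendance mask applied to
identical randomness — the common-random-numbers design that makes
scenario differences nearly noise-free.  Death ages are computed before any
screening is imposed and are bit-identical across scenarios (audited by an
equality test).

Screening visits are anchored to each woman's own even ages 40–74 (18
visits) rather than to calendar rounds; no programme start year is modelled.
A calendar-anchored variant would shift which diagnoses fall in the
1970–74 estimation window but not the lead-time mechanism itself.

Women whose tumour would never surface symptomatically before age 100 can
still be screen-detected; they carry an undefined lead time (excluded from
lead-time summaries, kept in detection proportions) and no cancer-death
clock, so their death is by other causes in every scenario.

## Design decisions that were genuinely open

- **Diagnosis window per scenario**: the 1970–74 window is applied after
  screening is imposed, so cohorts legitimately differ across scenarios
  (earlier detection moves diagnoses into and out of the window).
- **Relative bias**: averaged over per-replicate ratios; the ratio of
  replicate means is also reported (`relative_bias_of_means_pct`) since
  either reading of "bias divided by the no-screening estimate" is
  defensible.
- **Percentile intervals** are empirical 2.5/97.5 percentiles across
  replicates of the per-replicate differences (bias table) or point
  estimates (summary tables).
- **Carry-forward of life-table rates** beyond the last tabulated year
  stands in for mortality projections.

## Problem sizes

Default study conditions: 96 birth cohorts × 10,000 women, 200 replicates.
The `fast=True` profile used by the worked example and the end-to-end tests
scales this to 500 women per cohort and 20 replicates (≈ 150–200 diagnoses
per scenario-replicate), which preserves the sign and ordering of the bias
while keeping a full run around half a minute on one core.

## Known limitations

- With ≈ 150 diagnoses per desk-scale cohort the df-3 + time-dependent
  effect model is generously parameterised; occasional replicates fail the
  empty-ICSS-group or minimum-event checks and are skipped with a log entry.
- The generating model has a linear age effect; real breast-cancer excess
  hazards are U-shaped in age.
- No real survival benefit of screening is modelled (no stage shift), by
  design: the package measures the artefact, not the trade-off.
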