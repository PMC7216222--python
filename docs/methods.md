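# Methods

This note documents the models implemented in `koreicus`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real surveillance data.

## Population model

The simulator is a discrete-time (1-day step) mean-field model of four
female life stages per trap-coverage area: eggs E, larvae L, pupae P and
adult females A.  Each day, in this fixed order:

1. **survival** — every stage is multiplied by its temperature-dependent
   daily survival probability;
2. **density dependence** — surviving larvae are reduced by the
   Beverton–Holt factor 1/(1 + L/K), with K the year-specific
   carrying-capacity scaling (larvae per trap-coverage area);
3. **transitions** — a temperature-dependent fraction of eggs hatches, of
   larvae pupates, of pupae emerges as adults;
4. **oviposition** — surviving adults lay eggs at a temperature-dependent
   per-capita rate, multiplied by a 0.5 female sex ratio (the model is
   female-only).

The event order is arbitrary in principle but must be fixed for
reproducibility; it is stated here because the hand-computed single-step
oracle in the tests depends on it.  A 1-day discrete update was chosen over
an ODE formulation because all rates are daily and it avoids solver
tolerance decisions; runs are bit-reproducible.

**Thermal responses.**  Development and oviposition use Brière curves
c·T·(T−T₀)·√(T_max−T), clipped to zero outside (T₀, T_max); survival uses
s_max·exp(−((T−T_opt)/σ)²).  These are standard families in insect thermal
biology.  The laboratory-fitted curves for this species are not published
in a reusable form, so the default constants are this package's own
parameterisation, chosen to satisfy the qualitative constraints that are
published: the development optimum sits inside the favourable 23–28 °C
band (defaults peak near 27.5 °C with T₀ = 10 °C, T_max = 33 °C), eggs are
the robust overwintering-capable stage (broad survival curve,
s_max = 0.995, σ = 35 °C), adults live ~7–10 days at moderate temperatures
and suffer at hot ones (T_opt = 23 °C, σ = 10 °C), and populations at a
constant 25 °C out-perform both 15 °C and 35 °C.  Every constant lives in a
flat key-value config (`dev_larva.T0 = 10.0` style) so laboratory values
can be substituted verbatim.

**Initial conditions.**  There is no diapause mechanism; each season starts
from a configurable egg pool (default 5 000 eggs per trap-coverage area) on
April 1.  Both are conventions, not estimates; the April start predates the
first trapping sessions by a month, giving the egg pool time to hatch under
spring temperatures.  The absence of diapause means late-season abundance
is overestimated in principle; the mapping season therefore ends
September 30.

**Captures.**  Expected captures are C(t) = α·A(t) with α the daily capture
rate.  Captured females are not removed from the population: at α ≈ 1.5 %
per day the feedback is negligible, and keeping A unmodified makes C
exactly linear in α (a tested invariant).

## Calibration

Ψ = {α, K₂₀₁₇, K₂₀₁₈, K₂₀₁₉}; α is shared across years, K is year-specific.
The likelihood of the trap-averaged weekly captures n(m, y) is Poisson with
mean C(y, m, Ψ), multiplied across sessions and years.  Because n is an
average over 10 traps it is generally non-integer; log n! is continued as
log Γ(n+1), which is exact for integers and keeps the likelihood form
otherwise.  C = 0 with n > 0 yields −∞ rather than an exception so the
sampler can reject such proposals.

**Priors** (the analysis this package implements states none, so these are
deliberate choices): α ~ Uniform(0, 0.2) — generous around plausible
trap-removal rates — and K_y ~ log-Uniform(10, 10⁷), scale-free over the
physically plausible magnitudes.

**Sampler.**  Adaptive random-walk Metropolis on the transformed
coordinates (logit(α/0.2), log K_y), the smallest fully seedable scheme
that handles the strong α–K posterior correlation adequately.
Per-coordinate Gaussian proposal scales follow a Robbins–Monro recursion
(step t^(−0.6)) toward 30 % acceptance during burn-in and are frozen
afterwards, preserving detailed balance for the retained draws.  Chains
start from a data-informed point (α = 0.015; each log K profiled on a
coarse grid) plus jitter.  Two chains by default; split-chain Gelman–Rubin
R̂ is reported per parameter with a warning above 1.1; a chain that never
accepts raises a diagnostic error.  Defaults in the calibration tests and
the acceptance script are 20 000 iterations with 8 000 burn-in per chain,
which yields R̂ ≲ 1.1 on the synthetic studies; heavier runs only sharpen
the tails.

**Identifiability.**  α and K_y trade off along a likelihood ridge — more
mosquitoes trapped can mean a higher capture rate or a larger population.
Three seasons sharing one α constrain the ridge but do not remove it, so
the marginal posterior of α is wide.  This is faithful to the inference
problem, not a sampler artifact; the parameter-recovery test therefore
checks interval coverage of the generating values, not point accuracy.

**Predictive bands.**  For each retained Ψ draw the seasons are
re-simulated and one Poisson count is drawn per session; bands are the
2.5/25/75/97.5 percentiles of these samples.  Observation noise is included
because at weekly means below ~1 female the process-only bands would be
degenerately narrow.  Coverage counts sessions inside the bands with
inclusive endpoints, pooled across years.  With discrete low counts the
95 % band over-covers slightly (typically 96–99 % at the truth); this is a
property of Poisson quantiles, not miscalibration.

## Site-level statistics

Yearly per-site totals Y are regressed on windowed temperature means
(spring = Apr 1–May 31, summer = Jun 1–Aug 31) under Y ~ NB(µ, θ) with
log µ = a + bX and Var(Y) = µ + µ²/θ.  The fit alternates a statsmodels
GLM step (β given θ) with a univariate profile-likelihood update of θ,
the classical alternation for NB regression; a test cross-checks it
against a joint-ML fit.  Records are pooled across 2017–2019 (30
trap-years) by default.  The slope converts to an effect size as
100·(1 − exp(b·ΔT)) percent change for a ΔT warming.

Kendall correlations use tau-b with tie correction (ties are likely in
small count totals); p-values are exact for small untied samples and
tie-adjusted normal otherwise.  The correlation between captures and
human density / vegetation cover can be computed on per-trap totals pooled
over all years (default, matching how sparse counts are usually
aggregated) or on trap-year records — both are exposed because the right
aggregation is genuinely ambiguous at these sample sizes.

Buffer covariates use the cell-center-in-circle rule at 250 m radius:
human density is the sum of covered cells, vegetation cover the fraction
of covered cells in the three non-urban land-cover classes.  Cell-center
membership was preferred to area weighting for determinism and
testability; at 100 m cells against a 250 m radius the difference is at
most a few boundary cells.

## Abundance mapping

A trap samples Ω = πr² with r = 150 m daily flight range (Ω ≈ 7.07 ha);
the simulated adult abundance A(t) is per Ω, so the regional total is
A(t)·A_region/Ω.  Maps average A(t) over June 1–September 30.

The mapping pipeline kriges per-trap seasonal mean captures converted to
densities (captures / α / Ω, per hectare) using universal kriging with
human density as a linear drift, then rescales the surface by a single
constant so the hectare-integrated map equals the regional total — an
interpretation that uses all trap-level spatial signal while guaranteeing
exact mass consistency with the mechanistic model (conservation to 0.1 %
is a tested invariant).  The variogram is fitted to OLS drift residuals by
weighted least squares over exponential/spherical/Gaussian candidates
(weights = pair counts), falling back to an exponential with range = half
the maximum pairwise distance; the nugget defaults to 0, making the
predictor an exact interpolator at the traps (tested to 1e-6).  Negative
predictions are clipped to zero before rescaling; near-singular systems
(e.g. duplicated trap coordinates) are rejected by an explicit condition
check.  The mapped region A is whatever raster the user supplies, not an
administrative boundary.  Coordinates are planar metres; projections are
out of scope.

## Synthetic studies

The generator reproduces the study design the pipeline assumes: 10 traps,
three seasons (2017–2019), 20 weekly overnight sessions from May 1;
temperature as an annual sinusoid (mean 14 °C, amplitude 11 °C, peak
mid-July — summer means ≈ 24 °C) plus per-trap offsets (σ = 0.6 °C) and
AR(1) daily noise (ρ = 0.7, σ = 1.5 °C); human density as a smoothed
log-normal field at 100 m resolution, with the land-cover classes placed
so vegetation is anticorrelated with density.  Per-trap counts are
Poisson(α·A(t)·e_j) with mean-one log-normal trap effects (σ = 0.5,
reflecting the strong between-trap heterogeneity such surveys show)
multiplied by a negative human-density term (0.4 log-units per sd of log
density), so captures decline in busier neighbourhoods by construction.
The generating truth is α = 0.015 and K = {100, 225, 115}; the K values
were set so all-trap season totals land in the observed tens-to-~160
range with the middle year the most productive.  All generators are
bit-reproducible given the seed, with independent substreams per output.

Not emulated: satellite-retrieval artifacts in the temperatures, real city
geometry, trap micro-siting, overwinter carry-over between seasons, and
any mechanistic link between site temperature offsets and captures.
Passing the recovery tests therefore shows that the inference machinery
is correct and calibrated under the model's own assumptions — not that the
model is adequate for any particular real dataset.

## Numerical notes

* The calibration hot path pre-evaluates all thermal curves on the
  temperature series once (they do not depend on Ψ) and runs the daily
  update in plain floats; one likelihood evaluation costs ~0.1 ms.
* Test and acceptance problem sizes (20 000-iteration chains, 10
  recovery replicates, 60×60 or 30×30 grids) were chosen as the smallest
  sizes at which the statistical checks are stable.
* Percentiles everywhere are numpy's default linear-interpolation rule.
* Degenerate inputs fail loudly: temperature gaps, unordered sessions,
  negative stages, constant GLM predictors, all-tied rank data,
  zero-mass fields and buffers that miss the grid all raise typed errors
  rather than propagating NaNs.

## Known limitations

* No diapause, no between-season carry-over, no dispersal, males ignored.
* Thermal-response constants are qualitative stand-ins; conclusions about
  absolute abundance require substituting laboratory-fitted curves via the
  rate config.
* The α–K ridge limits what three seasons of one shared trap network can
  identify; informative priors on α (e.g. from mark–release–recapture)
  would sharpen K substantially.
* Kriging from 10 support points gives maps whose small-scale structure is
  dominated by the drift raster; the mass-conserving rescale guarantees
  totals, not local accuracy.
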