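# koreicus

Population dynamics, Bayesian calibration and city-scale abundance mapping
for the invasive mosquito *Aedes koreicus* in temperate urban areas.

The package is aimed at vector ecologists and surveillance modellers who
have weekly CO₂-trap captures of adult females, daily land-surface
temperatures at the trap sites, and human-density / land-cover rasters, and
who want (i) a mechanistic estimate of the seasonal population underlying
the captures and (ii) maps of adult-female density across the city.

## The model

A deterministic daily simulator tracks four life stages per trap-coverage
area — eggs E, larvae L, pupae P and adult females A.  Development
(hatching, pupation, emergence) and oviposition follow Brière thermal
curves c·T·(T−T₀)·√(T_max−T), zero outside the thermal window; daily
survival is Gaussian in temperature and bounded in [0, 1]; larval survival
carries a Beverton–Holt density-dependence factor 1/(1 + L/K).  Defaults
place the development optimum in the favourable 23–28 °C band and every
constant can be overridden from a flat config file.

Two parameters are free and estimated from data:

* **α** — the daily capture rate: the fraction of host-seeking adult
  females a trap removes per day, shared across years;
* **K_y** — the year-specific carrying-capacity scaling of the larval
  stage.

Given weekly trap-averaged captures n(m, y), the likelihood is Poisson
around the model-predicted captures C(y, m, Ψ) = α·A(t_m), multiplied over
sessions m and years y; Ψ = {α, K_y} is sampled by adaptive random-walk
Metropolis under α ~ U(0, 0.2) and log-uniform K priors, with Gelman–Rubin
diagnostics and posterior-predictive 50 %/95 % bands (Poisson observation
noise included) plus the pooled band-coverage statistic.

Around the mechanistic core sit the standard site-level analyses:
negative binomial GLMs (Y ~ NB(µ, θ), log µ = a + bX, Var = µ + µ²/θ) of
yearly totals on spring (Apr–May) or summer (Jun–Aug) temperature windows,
Kendall tau-b correlations with buffer-extracted human density and
vegetation cover, and universal kriging of trap-level densities with human
density as a drift.  A trap covers Ω = πr² (r = 150 m daily flight range,
Ω ≈ 7.07 ha); scaling the simulated abundance per Ω by A/Ω gives a city
total that the kriged map conserves exactly after rescaling.

A seeded synthetic-study generator (`koreicus.synthdata`) produces every
input the pipeline reads — temperatures, captures with known truth,
density/land-cover rasters, NB site tables — and is what the tests and the
acceptance script run on.

## Worked example

```python
import warnings
from koreicus import (SynthConfig, MCMCConfig, mcmc_sample,
                      posterior_summary, predictive_intervals, ci_coverage)
from koreicus.synthdata import gen_temperature, city_temperature, gen_captures

cfg = SynthConfig(seed=42)                      # truth: alpha = 0.015
temps = gen_temperature(cfg)                    # 3 years x 10 traps, daily degC
city = city_temperature(temps)
data, per_trap, _ = gen_captures(cfg, temps)    # weekly Poisson captures

ps = mcmc_sample(data, city,
                 MCMCConfig(n_iter=20_000, burn_in=8_000, seed=0),
                 template=cfg.true_params())
print(posterior_summary(ps).round(3))
bands = predictive_intervals(ps, city, data.sessions, n_draws=400, seed=0)
print(ci_coverage(data, bands))
```

prints

```
              mean    q2.5    q97.5   rhat
parameter
alpha        0.044   0.005    0.126  1.024
K2017       86.229  10.961  431.198  1.015
K2018      182.592  17.432  882.092  1.014
K2019       68.724  10.759  341.749  1.014
{'frac95': 0.9833333333333333, 'frac50': 0.8833333333333333}
```

The generating capture rate α = 0.015 lies inside its 95 % credible
interval (0.005–0.126); the interval is wide because α trades off against
the K_y along a likelihood ridge — only their combination is strongly
identified by trap counts alone.  K_2018 is the largest of the three, as
designed (the middle season is the most productive), and 98 % / 88 % of
the observed weekly captures fall inside the 95 % / 50 % posterior-
predictive bands.

The same pipeline is available from the shell:

```sh
koreicus all --seed 3 --outdir run1
```

which writes the synthetic study, the MCMC chains and summary, a tidy
statistics table (GLM slopes and Kendall taus) and per-year abundance maps
(`abundance_2017.asc`, ...) as ESRI ASCII grids.

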