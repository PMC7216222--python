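"""Bayesian calibration of the population model to weekly trap captures.

The estimand is Ψ = {alpha, K_y for each modelled year}: the daily
capture rate (shared across years) and the year-specific larval
carrying-capacity scalings.  The observation model is a Poisson
likelihood of the trap-averaged weekly captures n(m, y) given the
model-predicted captures C(y, m, Ψ) = alpha · A(t_m), multiplied across
sessions m and years y.  Because n is an average over the 10 traps it
need not be an integer; the likelihood uses the continuous extension of
log n! via log Γ(n + 1), which is exact for integer counts.

Priors (the study itself states none): alpha ~ Uniform(0, 0.2),
K_y ~ log-Uniform(10, 1e7), independent.  Sampling is adaptive
random-walk Metropolis on the transformed coordinates
(logit(alpha/0.2), log K_y), with per-coordinate proposal scales tuned
toward a 30 % acceptance rate during burn-in and frozen afterwards.
Convergence is monitored with the Gelman–Rubin statistic across ≥ 2
chains.

Posterior-predictive bands include Poisson observation noise (one count
drawn per retained Ψ and session), which keeps the intervals
non-degenerate at the low counts typical of these data; the coverage
statistic is the pooled fraction of observed sessions falling inside
the 50 % / 95 % bands (inclusive bounds).
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .popmodel import (
    InputError,
    ParameterSet,
    TemperatureSeries,
    simulate_from_daily_rates,
)

__all__ = [
    "CaptureData",
    "PosteriorSample",
    "PredictiveBand",
    "MCMCConfig",
    "CalibrationError",
    "load_capture_csv",
    "log_likelihood",
    "log_prior",
    "mcmc_sample",
    "posterior_summary",
    "predictive_intervals",
    "ci_coverage",
]

ALPHA_MAX = 0.2          # upper prior bound on the daily capture rate
K_MIN, K_MAX = 10.0, 1e7  # log-uniform prior support for K


class CalibrationError(RuntimeError):
    """Sampler diagnostic failure (e.g. a chain that never accepts)."""


# ---------------------------------------------------------------------------
# Observed captures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaptureData:
    """Per-year trapping sessions and trap-averaged observed counts.

    ``n_avg[year][m]`` is the across-trap mean capture of session ``m``;
    averages over 10 traps are non-negative reals, not integers.
    """

    sessions: Mapping[int, tuple[dt.date, ...]]
    n_avg: Mapping[int, np.ndarray]

    def __post_init__(self) -> None:
        sessions = {int(y): tuple(d) for y, d in self.sessions.items()}
        n_avg = {int(y): np.asarray(v, dtype=float) for y, v in self.n_avg.items()}
        if set(sessions) != set(n_avg):
            raise InputError("sessions and n_avg must cover the same years")
        for y in sessions:
            dates, vals = sessions[y], n_avg[y]
            if len(dates) != vals.size:
                raise InputError(f"year {y}: {len(dates)} sessions but {vals.size} counts")
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise InputError(f"year {y}: sessions must be strictly increasing")
            if vals.size and (vals.min() < 0 or not np.all(np.isfinite(vals))):
                raise InputError(f"year {y}: counts must be finite and ≥ 0")
        object.__setattr__(self, "sessions", sessions)
        object.__setattr__(self, "n_avg", n_avg)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.sessions))

    @property
    def n_sessions(self) -> int:
        return sum(len(d) for d in self.sessions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "session_date": d, "n_avg": v}
            for y in self.years
            for d, v in zip(self.sessions[y], self.n_avg[y])
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_trap_frame(cls, df: pd.DataFrame) -> "CaptureData":
        """Build trap-averaged data from per-trap rows (trap_id, date, count)."""
        required = {"trap_id", "date", "count"}
        if not required.issubset(df.columns):
            raise InputError(f"capture table needs columns {sorted(required)}")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"]).dt.date
        if (df["count"] < 0).any():
            raise InputError("capture counts must be ≥ 0")
        avg = df.groupby("date")["count"].mean()
        sessions: dict[int, list[dt.date]] = {}
        values: dict[int, list[float]] = {}
        for day, v in avg.items():
            sessions.setdefault(day.year, []).append(day)
            values.setdefault(day.year, []).append(float(v))
        return cls(
            {y: tuple(sorted(d)) for y, d in sessions.items()},
            {y: np.array([v for _, v in sorted(zip(sessions[y], values[y]))])
             for y in sessions},
        )


def load_capture_csv(path) -> CaptureData:
    """Read a per-trap ``trap_id,date,count`` CSV into trap-averaged data."""
    return CaptureData.from_trap_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Likelihood and prior
# ---------------------------------------------------------------------------

class _SeasonCache:
    """Pre-evaluated daily rates and session indices for one year.

    The thermal responses depend on temperature only, so they are shared
    by every (alpha, K) proposal; only the sequential daily update needs
    rerunning inside the sampler.
    """

    def __init__(self, temps: TemperatureSeries, sessions: Sequence[dt.date],
                 template: ParameterSet, year: int):
        start = template.season_start_date(year)
        season = temps.slice(start, temps.end_date)
        self.idx = np.array([season.index_of(d) for d in sessions], dtype=int)
        # no session looks past its own date: truncate the simulated span
        last = int(self.idx.max()) + 1 if self.idx.size else len(season)
        self.daily = template.rates.daily(season.values[:last])
        self.init_eggs = template.init_eggs
        self.sex_ratio = template.rates.sex_ratio

    def adults(self, K: float) -> np.ndarray:
        states = simulate_from_daily_rates(
            self.daily, K, self.init_eggs, self.sex_ratio
        )
        return states[self.idx, 3]


def _build_caches(psi: ParameterSet, data: CaptureData,
                  temps_by_year: Mapping[int, TemperatureSeries]):
    caches = {}
    for year in data.years:
        if year not in temps_by_year:
            raise InputError(f"no temperature series for year {year}")
        caches[year] = _SeasonCache(temps_by_year[year], data.sessions[year], psi, year)
    return caches


def _poisson_loglik(n: np.ndarray, C: np.ndarray) -> float:
    """Σ [n log C − C − log Γ(n+1)], with the conventions 0·log 0 = 0 and
    C = 0, n > 0 ⇒ −inf."""
    C = np.asarray(C, float)
    n = np.asarray(n, float)
    if np.any((C <= 0) & (n > 0)):
        return -math.inf
    pos = n > 0
    ll = -C.sum() - gammaln(n + 1.0).sum()
    ll += float(np.sum(n[pos] * np.log(C[pos])))
    return float(ll)


def log_likelihood(psi: ParameterSet, data: CaptureData,
                   temps_by_year: Mapping[int, TemperatureSeries]) -> float:
    """Poisson log-likelihood of the averaged weekly captures, summed
    (multiplied on the natural scale) across all modelled years."""
    caches = _build_caches(psi, data, temps_by_year)
    total = 0.0
    for year in data.years:
        C = psi.alpha * caches[year].adults(psi.K_for(year))
        total += _poisson_loglik(data.n_avg[year], C)
        if total == -math.inf:
            break
    return total


def predicted_captures(psi: ParameterSet, data: CaptureData,
                       temps_by_year: Mapping[int, TemperatureSeries],
                       ) -> dict[int, np.ndarray]:
    """Model-predicted captures C(y, m, Ψ) for every observed session."""
    caches = _build_caches(psi, data, temps_by_year)
    return {y: psi.alpha * caches[y].adults(psi.K_for(y)) for y in data.years}


_LOG_K_RANGE = math.log(K_MAX / K_MIN)


def log_prior(psi: ParameterSet) -> float:
    """alpha ~ U(0, ALPHA_MAX); each K ~ log-U(K_MIN, K_MAX); −inf outside."""
    if not (0.0 <= psi.alpha <= ALPHA_MAX):
        return -math.inf
    lp = -math.log(ALPHA_MAX)
    for K in psi.K_by_year.values():
        if not (K_MIN <= K <= K_MAX):
            return -math.inf
        lp += -math.log(K) - math.log(_LOG_K_RANGE)
    return lp


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings (adaptive random-walk Metropolis)."""

    n_iter: int = 50_000
    burn_in: int = 20_000
    n_chains: int = 2
    seed: int = 0
    init_scale: float = 0.15   # initial proposal sd in transformed space
    target_accept: float = 0.30
    rhat_warn: float = 1.1

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise InputError("n_iter must exceed burn_in")
        if self.n_chains < 2:
            raise InputError("need at least 2 chains for convergence diagnostics")


@dataclass(frozen=True)
class PosteriorSample:
    """Retained (post-burn-in) MCMC draws of Ψ = (alpha, K_y...)."""

    years: tuple[int, ...]
    chains: np.ndarray          # (n_chains, n_kept, 1 + n_years)
    log_post: np.ndarray        # (n_chains, n_kept)
    seed: int
    acceptance: tuple[float, ...]
    rhat: dict[str, float]
    template: ParameterSet

    @property
    def param_names(self) -> tuple[str, ...]:
        return ("alpha",) + tuple(f"K{y}" for y in self.years)

    @property
    def n_draws(self) -> int:
        return self.chains.shape[0] * self.chains.shape[1]

    def flat(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[2])

    def parameter_set(self, draw: np.ndarray) -> ParameterSet:
        return ParameterSet(
            alpha=float(draw[0]),
            K_by_year={y: float(draw[1 + i]) for i, y in enumerate(self.years)},
            rates=self.template.rates,
            init_eggs=self.template.init_eggs,
            season_start=self.template.season_start,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.chains.shape[0]):
            df = pd.DataFrame(self.chains[c], columns=list(self.param_names))
            df.insert(0, "iter", np.arange(self.chains.shape[1]))
            df.insert(0, "chain", c)
            df["log_post"] = self.log_post[c]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor R̂ for one parameter."""
    half = chains.shape[1] // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def _initial_point(caches, data: CaptureData, years, alpha0: float = 0.015):
    """Data-informed start: profile each log K on a coarse grid at alpha0."""
    z = [float(logit(alpha0 / ALPHA_MAX))]
    grid = np.linspace(math.log(K_MIN) + 0.1, math.log(K_MAX) - 0.1, 61)
    for y in years:
        lls = [
            _poisson_loglik(data.n_avg[y], alpha0 * caches[y].adults(math.exp(g)))
            for g in grid
        ]
        z.append(float(grid[int(np.argmax(lls))]))
    return np.array(z)


def mcmc_sample(data: CaptureData,
                temps_by_year: Mapping[int, TemperatureSeries],
                config: MCMCConfig | None = None,
                template: ParameterSet | None = None) -> PosteriorSample:
    """Sample the posterior of Ψ by adaptive random-walk Metropolis.

    Proposals are diagonal Gaussians on (logit(alpha/0.2), log K_y); the
    per-coordinate scales follow a Robbins–Monro recursion toward the
    target acceptance rate during burn-in and are frozen afterwards.
    Fully reproducible given ``config.seed``.
    """
    config = config or MCMCConfig()
    years = data.years
    if template is None:
        template = ParameterSet(alpha=0.01, K_by_year={y: 1e4 for y in years})
    caches = _build_caches(template, data, temps_by_year)
    ndim = 1 + len(years)
    zlo = np.array([-math.inf] + [math.log(K_MIN)] * len(years))
    zhi = np.array([math.inf] + [math.log(K_MAX)] * len(years))

    def log_target(z: np.ndarray) -> float:
        if np.any(z < zlo) or np.any(z > zhi):
            return -math.inf
        alpha = ALPHA_MAX * float(expit(z[0]))
        ll = 0.0
        for i, y in enumerate(years):
            C = alpha * caches[y].adults(math.exp(z[1 + i]))
            ll += _poisson_loglik(data.n_avg[y], C)
            if ll == -math.inf:
                return -math.inf
        # log-uniform K is flat in log K; the alpha-uniform prior pulled
        # back through the logit transform contributes log s(1-s)
        s = float(expit(z[0]))
        return ll + math.log(max(s * (1.0 - s), 1e-300))

    z_center = _initial_point(caches, data, years)
    n_keep = config.n_iter - config.burn_in
    chains = np.empty((config.n_chains, n_keep, ndim))
    log_post = np.empty((config.n_chains, n_keep))
    acceptance = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        z = z_center + 0.1 * rng.standard_normal(ndim)
        z = np.clip(z, zlo + 1e-9, zhi - 1e-9)
        lp = log_target(z)
        scales = np.full(ndim, config.init_scale)
        accepted_post = 0
        for it in range(config.n_iter):
            prop = z + scales * rng.standard_normal(ndim)
            lp_prop = log_target(prop)
            accept = lp_prop - lp > math.log(rng.random() + 1e-300)
            if accept:
                z, lp = prop, lp_prop
            if it < config.burn_in:
                gamma = (it + 1) ** -0.6
                scales *= math.exp(gamma * ((1.0 if accept else 0.0) - config.target_accept))
                scales = np.clip(scales, 1e-4, 10.0)
            else:
                k = it - config.burn_in
                alpha = ALPHA_MAX * float(expit(z[0]))
                chains[c, k, 0] = alpha
                chains[c, k, 1:] = np.exp(z[1:])
                log_post[c, k] = lp
                accepted_post += int(accept)
        rate = accepted_post / n_keep
        if rate == 0.0:
            raise CalibrationError(
                f"chain {c}: no proposal accepted after burn-in (degenerate scales)"
            )
        acceptance.append(rate)

    names = ("alpha",) + tuple(f"K{y}" for y in years)
    rhat = {
        name: _gelman_rubin(chains[:, :, j]) for j, name in enumerate(names)
    }
    bad = {k: v for k, v in rhat.items() if v > config.rhat_warn}
    if bad:
        warnings.warn(
            f"Gelman–Rubin R̂ above {config.rhat_warn}: {bad}; "
            "chains may not have converged",
            stacklevel=2,
        )
    return PosteriorSample(
        years=years,
        chains=chains,
        log_post=log_post,
        seed=config.seed,
        acceptance=tuple(acceptance),
        rhat=rhat,
        template=template,
    )


# ---------------------------------------------------------------------------
# Posterior summaries and predictive checks
# ---------------------------------------------------------------------------

def posterior_summary(ps: PosteriorSample, min_draws: int = 100) -> pd.DataFrame:
    """Per-parameter posterior mean and central 95 % credible interval."""
    flat = ps.flat()
    if flat.shape[0] < min_draws:
        raise InputError(f"need ≥ {min_draws} retained draws, have {flat.shape[0]}")
    rows = []
    for j, name in enumerate(ps.param_names):
        col = flat[:, j]
        lo, hi = np.percentile(col, [2.5, 97.5])
        rows.append(
            {"parameter": name, "mean": col.mean(), "q2.5": lo, "q97.5": hi,
             "rhat": ps.rhat[name]}
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class PredictiveBand:
    """Posterior-predictive capture intervals for one year's sessions."""

    sessions: tuple[dt.date, ...]
    mean: np.ndarray
    lo95: np.ndarray
    lo50: np.ndarray
    hi50: np.ndarray
    hi95: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.mean, self.lo95, self.lo50, self.hi50, self.hi95]
        if any(a.size != len(self.sessions) for a in arrays):
            raise InputError("band arrays must align with sessions")
        if np.any(self.lo95 > self.lo50) or np.any(self.hi50 > self.hi95) \
                or np.any(self.lo50 > self.hi50):
            raise InputError("50% interval must nest inside the 95% interval")
        if np.any(self.lo95 < 0):
            raise InputError("band bounds must be ≥ 0")


def predictive_intervals(ps: PosteriorSample,
                         temps_by_year: Mapping[int, TemperatureSeries],
                         session_dates: Mapping[int, Sequence[dt.date]],
                         n_draws: int = 500,
                         seed: int = 0,
                         observation_noise: bool = True,
                         ) -> dict[int, PredictiveBand]:
    """Posterior-predictive 50 % / 95 % capture bands per session.

    For each retained Ψ draw the season is re-simulated, the predicted
    captures C are computed, and (optionally) one Poisson count is drawn
    per session; the bands are percentiles of those samples.
    """
    flat = ps.flat()
    if n_draws > flat.shape[0]:
        raise InputError(f"n_draws={n_draws} exceeds available draws {flat.shape[0]}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(flat.shape[0], size=n_draws, replace=False)
    dummy = CaptureData(
        {y: tuple(session_dates[y]) for y in session_dates},
        {y: np.zeros(len(session_dates[y])) for y in session_dates},
    )
    caches = _build_caches(ps.template, dummy, temps_by_year)
    out: dict[int, PredictiveBand] = {}
    samples = {y: np.empty((n_draws, len(session_dates[y]))) for y in session_dates}
    for r, row in enumerate(flat[pick]):
        alpha = row[0]
        for i, y in enumerate(ps.years):
            if y not in session_dates:
                continue
            C = alpha * caches[y].adults(row[1 + i])
            samples[y][r] = rng.poisson(C) if observation_noise else C
    for y in session_dates:
        mat = samples[y]
        lo95, lo50, hi50, hi95 = np.percentile(mat, [2.5, 25.0, 75.0, 97.5], axis=0)
        out[y] = PredictiveBand(
            sessions=tuple(session_dates[y]),
            mean=mat.mean(axis=0),
            lo95=lo95, lo50=lo50, hi50=hi50, hi95=hi95,
        )
    return out


def ci_coverage(observed: CaptureData,
                bands: Mapping[int, PredictiveBand]) -> dict[str, float]:
    """Pooled fraction of observed sessions inside the 95 % and 50 % bands."""
    in95 = in50 = total = 0
    for y in observed.years:
        if y not in bands:
            raise InputError(f"no predictive band for year {y}")
        band = bands[y]
        if band.sessions != observed.sessions[y]:
            raise InputError(f"year {y}: band sessions do not match observations")
        n = observed.n_avg[y]
        in95 += int(np.sum((n >= band.lo95) & (n <= band.hi95)))
        in50 += int(np.sum((n >= band.lo50) & (n <= band.hi50)))
        total += n.size
    if total == 0:
        raise InputError("no sessions to score")
    return {"frac95": in95 / total, "frac50": in50 / total}
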