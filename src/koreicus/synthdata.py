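"""Seeded generators for a complete synthetic trapping study.

The generators emulate the study design the pipeline expects: about 10
CO₂-baited traps operated weekly overnight from May to September (≈ 20
sessions per year) over three seasons, in a temperate city with a mean
annual temperature of 14 °C, low seasonal capture totals (tens to ~160
females across all traps), and a positive human-density surface that is
negatively associated with captures through the spatial placement of
vegetation.

Everything is deterministic given the seed: per-stream generators are
derived from ``numpy.random.SeedSequence(seed, stream...)`` so the
output of one generator never depends on whether another was called.

What is emulated — and what is not: seasonal temperature forcing with
AR(1) daily weather noise, fixed multiplicative trap effects (observed
between-trap heterogeneity), Poisson observation noise around the
model-predicted captures, smooth log-normal human-density fields, and
NB-distributed yearly totals.  Real MODIS retrieval artifacts, city
geometry, trap micro-siting and overwintering carry-over between years
are not emulated.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calibrate import CaptureData
from .popmodel import (
    ParameterSet,
    RateCurveSet,
    TemperatureSeries,
    Trajectory,
    default_rates,
    simulate_season,
)
from .sitestats import VEGETATION_CLASSES
from .spatial import GridField

__all__ = [
    "SynthConfig",
    "gen_temperature",
    "city_temperature",
    "gen_captures",
    "gen_density_grid",
    "gen_site_table",
    "gen_trap_coords",
    "write_temperature_csv",
    "write_capture_csv",
]

# stream ids for independent generator substreams
_STREAM_TEMP, _STREAM_CAPT, _STREAM_GRID, _STREAM_GLM, _STREAM_COORD = range(5)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design constants for the synthetic generators.

    Temperature: an annual sinusoid with mean 14 °C and amplitude 11 °C
    peaking in mid-July (day 196), giving June–August means near 24 °C,
    plus a per-trap offset and AR(1) daily noise.  The true parameter
    set uses alpha = 0.015 (about 1.5 % of host-seeking females captured
    per trap-day); the year-specific K defaults are set so that
    simulated all-trap season totals fall in the observed 60–160 range,
    with the middle year the most productive.
    """

    seed: int = 0
    n_traps: int = 10
    years: tuple[int, ...] = (2017, 2018, 2019)
    sessions_per_year: int = 20
    session_start: tuple[int, int] = (5, 1)   # first weekly session (month, day)
    # temperature profile
    temp_mean: float = 14.0
    temp_amplitude: float = 11.0
    temp_peak_doy: int = 196                  # mid-July
    trap_offset_sd: float = 0.6
    ar1_rho: float = 0.7
    noise_sd: float = 1.5
    year_offset_sd: float = 0.4
    # observation process
    true_alpha: float = 0.015
    true_K: Mapping[int, float] = field(
        default_factory=lambda: {2017: 100.0, 2018: 225.0, 2019: 115.0}
    )
    trap_effect_sd: float = 0.5               # log-scale sd of trap effects
    density_effect: float = 0.4               # log-capture decrease per sd of log density
    rates: RateCurveSet = field(default_factory=default_rates)
    init_eggs: float = 5000.0
    # rasters
    grid_rows: int = 60
    grid_cols: int = 60
    cellsize: float = 100.0
    density_mean: float = 25.0                # persons per 100 m cell
    density_log_sd: float = 0.8
    smooth_cells: float = 5.0
    # NB GLM truth
    glm_a: float = 2.0
    glm_b: float = -0.5
    glm_theta: float = 1.5

    def true_params(self) -> ParameterSet:
        return ParameterSet(
            alpha=self.true_alpha,
            K_by_year=dict(self.true_K),
            rates=self.rates,
            init_eggs=self.init_eggs,
        )

    def session_dates(self, year: int) -> tuple[dt.date, ...]:
        first = dt.date(year, *self.session_start)
        return tuple(first + dt.timedelta(days=7 * k)
                     for k in range(self.sessions_per_year))

    def _rng(self, stream: int, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream, *key]))


# ---------------------------------------------------------------------------
# Temperature
# ---------------------------------------------------------------------------

def _sinusoid(cfg: SynthConfig, doys: np.ndarray) -> np.ndarray:
    return cfg.temp_mean + cfg.temp_amplitude * np.cos(
        2.0 * math.pi * (doys - cfg.temp_peak_doy) / 365.0
    )


def gen_temperature(cfg: SynthConfig) -> dict[int, dict[str, TemperatureSeries]]:
    """Daily series per year and trap, covering Jan 1 – Dec 31.

    T(d) = seasonal sinusoid + trap offset + year offset + AR(1) noise.
    With the noise and offsets off, the annual mean equals ``temp_mean``.
    """
    out: dict[int, dict[str, TemperatureSeries]] = {}
    for year in cfg.years:
        n_days = (dt.date(year, 12, 31) - dt.date(year, 1, 1)).days + 1
        doys = np.arange(1, n_days + 1, dtype=float)
        base = _sinusoid(cfg, doys)
        rng_year = cfg._rng(_STREAM_TEMP, year)
        year_off = cfg.year_offset_sd * rng_year.standard_normal()
        # shared daily weather noise (AR(1)) for all traps, plus trap offsets
        eps = rng_year.standard_normal(n_days)
        noise = np.empty(n_days)
        noise[0] = eps[0]
        for t in range(1, n_days):
            noise[t] = cfg.ar1_rho * noise[t - 1] + eps[t]
        noise *= cfg.noise_sd * math.sqrt(1.0 - cfg.ar1_rho**2)
        per_trap: dict[str, TemperatureSeries] = {}
        for i in range(cfg.n_traps):
            trap = chr(ord("A") + i)
            rng_trap = cfg._rng(_STREAM_TEMP, year, i)
            offset = cfg.trap_offset_sd * rng_trap.standard_normal()
            per_trap[trap] = TemperatureSeries(
                dt.date(year, 1, 1), base + year_off + offset + noise
            )
        out[year] = per_trap
    return out


def city_temperature(temps: Mapping[int, Mapping[str, TemperatureSeries]],
                     ) -> dict[int, TemperatureSeries]:
    """Across-trap unweighted mean series per year."""
    from .popmodel import city_mean_series

    return {year: city_mean_series(per_trap) for year, per_trap in temps.items()}


# ---------------------------------------------------------------------------
# Captures
# ---------------------------------------------------------------------------

def gen_captures(cfg: SynthConfig,
                 temps: Mapping[int, Mapping[str, TemperatureSeries]] | None = None,
                 ) -> tuple[CaptureData, pd.DataFrame, dict[int, Trajectory]]:
    """Simulate the population per year and draw per-trap Poisson captures.

    Per trap j and session t the count is Poisson(alpha · A(t) · e_j).
    The fixed trap effects e_j combine mean-one log-normal heterogeneity
    with a negative dependence on the (standardised) log human density
    at the trap site, so that busier neighbourhoods yield systematically
    fewer captures.  Returns the trap-averaged :class:`CaptureData`, the
    per-trap long table (trap_id, date, count), and the generating
    trajectories.
    """
    if temps is None:
        temps = gen_temperature(cfg)
    city = city_temperature(temps)
    psi = cfg.true_params()
    rng = cfg._rng(_STREAM_CAPT)
    effects = np.exp(cfg.trap_effect_sd * rng.standard_normal(cfg.n_traps)
                     - 0.5 * cfg.trap_effect_sd**2)
    if cfg.density_effect != 0.0:
        density, _ = gen_density_grid(cfg)
        coords = gen_trap_coords(cfg)
        logd = np.array([math.log(density.value_at(*coords[chr(ord("A") + i)]))
                         for i in range(cfg.n_traps)])
        z = (logd - logd.mean()) / max(logd.std(), 1e-12)
        # -c^2/2 centres the factor so the across-trap mean effect stays ~1
        effects *= np.exp(-cfg.density_effect * z - 0.5 * cfg.density_effect**2)
    trajectories: dict[int, Trajectory] = {}
    sessions: dict[int, tuple[dt.date, ...]] = {}
    n_avg: dict[int, np.ndarray] = {}
    rows = []
    for year in cfg.years:
        traj = simulate_season(city[year], psi, year)
        trajectories[year] = traj
        dates = cfg.session_dates(year)
        sessions[year] = dates
        expected = cfg.true_alpha * traj.adults_on(dates)
        counts = rng.poisson(expected[None, :] * effects[:, None])  # traps × sessions
        n_avg[year] = counts.mean(axis=0)
        for i in range(cfg.n_traps):
            trap = chr(ord("A") + i)
            for d, c in zip(dates, counts[i]):
                rows.append({"trap_id": trap, "date": d, "count": int(c)})
    data = CaptureData(sessions, n_avg)
    return data, pd.DataFrame(rows), trajectories


# ---------------------------------------------------------------------------
# Rasters and trap coordinates
# ---------------------------------------------------------------------------

def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int],
                       sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise with ~unit marginal variance.

    Normalisation uses the analytic variance reduction of a Gaussian
    filter on white noise, 1/(4π σ²), rather than the empirical standard
    deviation, so the field genuinely flattens to a constant as the
    smoothing length grows beyond the grid.
    """
    z = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    z -= z.mean()
    return z * (2.0 * math.sqrt(math.pi) * max(sigma, 0.5))


def gen_density_grid(cfg: SynthConfig) -> tuple[GridField, GridField]:
    """Correlated human-density and land-cover rasters.

    Density is a smoothed log-normal random field (strictly positive).
    Land cover assigns the two urban classes where the density-driving
    field is high and the three vegetation classes where it is low, so
    vegetation fraction is negatively correlated with human density.
    """
    rng = cfg._rng(_STREAM_GRID)
    shape = (cfg.grid_rows, cfg.grid_cols)
    z = _smooth_unit_field(rng, shape, cfg.smooth_cells)
    density = cfg.density_mean * np.exp(cfg.density_log_sd * z
                                        - 0.5 * cfg.density_log_sd**2)
    w = _smooth_unit_field(rng, shape, cfg.smooth_cells / 2.0)
    urban_score = z + 0.6 * w
    q = np.quantile(urban_score, [0.35, 0.55, 0.70, 0.85])
    landcover = np.full(shape, 5.0)
    landcover[urban_score > q[0]] = 4.0
    landcover[urban_score > q[1]] = 3.0
    landcover[urban_score > q[2]] = 2.0
    landcover[urban_score > q[3]] = 1.0
    dens = GridField(0.0, 0.0, cfg.cellsize, density, units="persons/cell")
    cover = GridField(0.0, 0.0, cfg.cellsize, landcover, units="class id")
    return dens, cover


def gen_trap_coords(cfg: SynthConfig, margin_cells: int = 5,
                    ) -> dict[str, tuple[float, float]]:
    """Trap coordinates scattered inside the grid, away from the border."""
    rng = cfg._rng(_STREAM_COORD)
    x0 = margin_cells * cfg.cellsize
    x1 = (cfg.grid_cols - margin_cells) * cfg.cellsize
    y1 = (cfg.grid_rows - margin_cells) * cfg.cellsize
    coords = {}
    for i in range(cfg.n_traps):
        trap = chr(ord("A") + i)
        coords[trap] = (float(rng.uniform(x0, x1)), float(rng.uniform(x0, y1)))
    return coords


# ---------------------------------------------------------------------------
# NB-GLM site tables
# ---------------------------------------------------------------------------

def gen_site_table(cfg: SynthConfig, n: int | None = None,
                   x: np.ndarray | None = None) -> pd.DataFrame:
    """Draw Y ~ NB(µ = exp(a + bX), θ) records with the truth attached.

    ``x`` defaults to uniform summer-temperature-like values in
    [21, 27] °C.  The NB draw uses the gamma–Poisson mixture, so
    E(Y) = µ and Var(Y) = µ + µ²/θ exactly.
    """
    if cfg.glm_theta <= 0:
        raise ValueError("theta must be positive")
    rng = cfg._rng(_STREAM_GLM)
    if x is None:
        n = 30 if n is None else n
        x = rng.uniform(21.0, 27.0, size=n)
    x = np.asarray(x, float)
    mu = np.exp(cfg.glm_a + cfg.glm_b * x)
    lam = rng.gamma(shape=cfg.glm_theta, scale=mu / cfg.glm_theta)
    y = rng.poisson(lam)
    return pd.DataFrame({
        "summer_lst": x,
        "Y": y.astype(int),
        "true_mu": mu,
        "true_a": cfg.glm_a,
        "true_b": cfg.glm_b,
        "true_theta": cfg.glm_theta,
    })


# ---------------------------------------------------------------------------
# Writers (pipeline-schema CSVs)
# ---------------------------------------------------------------------------

def write_temperature_csv(temps: Mapping[int, Mapping[str, TemperatureSeries]],
                          path) -> None:
    rows = []
    for year in sorted(temps):
        for trap in sorted(temps[year]):
            ts = temps[year][trap]
            for d, v in zip(ts.dates, ts.values):
                rows.append({"trap_id": trap, "date": d.isoformat(),
                             "temp_c": round(float(v), 3)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_capture_csv(per_trap: pd.DataFrame, path) -> None:
    df = per_trap.copy()
    df["date"] = [d.isoformat() if hasattr(d, "isoformat") else str(d)
                  for d in df["date"]]
    df.to_csv(path, index=False)
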