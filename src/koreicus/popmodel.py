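"""Stage-structured, temperature-driven population model for *Aedes koreicus*.

The model tracks daily abundances of four life stages — eggs (E), larvae
(L), pupae (P) and adult females (A) — as continuous (mean-field)
quantities per trap-coverage area.  All development and mortality rates
are deterministic functions of the daily mean temperature; larval
survival is additionally density dependent through a Beverton–Holt
factor ``1/(1 + L/K)`` with a year-specific carrying-capacity scaling
``K``.  Two free parameters are estimated from trap data: the daily
capture rate ``alpha`` of host-seeking females (shared across years) and
``K`` (one per year); everything else is a fixed thermal-response curve.

Thermal responses use two standard families from insect thermal biology:

* development (egg hatch, larval development, pupal emergence) and
  oviposition follow Brière curves ``c * T * (T - T0) * sqrt(Tmax - T)``,
  clipped to zero outside the thermal window ``(T0, Tmax)``;
* daily survival probabilities are Gaussian in temperature,
  ``s_max * exp(-((T - T_opt)/sigma)^2)``, bounded in ``[0, 1]``.

Default constants are chosen so that development peaks between 23 and
28 °C, the range reported as favourable for this species, and can be
overridden from a flat key-value config file so laboratory-fitted
constants can be substituted verbatim.

Each simulated day applies, in this fixed order: (1) temperature-driven
survival of every stage, (2) density-dependent reduction of the
surviving larvae, (3) stage transitions (hatching, pupation, emergence),
(4) oviposition by surviving adults into the egg pool, multiplied by a
0.5 female sex ratio (the model is female-only).  Trapping removes a
negligible fraction of adults (about 1.5 % per day) and is therefore not
fed back into the dynamics: expected captures are simply
``C(t) = alpha * A(t)``.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "InputError",
    "InvariantError",
    "TemperatureSeries",
    "StageState",
    "BriereCurve",
    "SurvivalCurve",
    "RateCurveSet",
    "ParameterSet",
    "Trajectory",
    "make_curve",
    "eval_rate",
    "default_rates",
    "rates_from_config",
    "rates_to_config",
    "step_day",
    "simulate_season",
    "expected_captures",
    "load_temperature_csv",
    "city_mean_series",
]

TEMP_MIN, TEMP_MAX = -40.0, 60.0  # physical plausibility bounds, °C


class ConfigurationError(ValueError):
    """Invalid model configuration (unknown curve family, bad constant)."""


class InputError(ValueError):
    """Invalid user input (gaps, misaligned dates, out-of-range values)."""


class InvariantError(ValueError):
    """A model-state invariant (non-negativity, finiteness) was violated."""


# ---------------------------------------------------------------------------
# Temperature driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily mean temperatures (°C) starting at ``start_date``."""

    start_date: dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise InputError("temperature series must be a non-empty 1-d array")
        if not np.all(np.isfinite(vals)):
            raise InputError("temperature series contains non-finite values")
        if vals.min() < TEMP_MIN or vals.max() > TEMP_MAX:
            raise InputError(
                f"temperatures outside [{TEMP_MIN}, {TEMP_MAX}] °C are not physical"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=len(self) - 1)

    @property
    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(len(self))]

    def index_of(self, day: dt.date) -> int:
        i = (day - self.start_date).days
        if i < 0 or i >= len(self):
            raise InputError(f"date {day} outside series {self.start_date}..{self.end_date}")
        return i

    def value_on(self, day: dt.date) -> float:
        return float(self.values[self.index_of(day)])

    def slice(self, start: dt.date, end: dt.date) -> "TemperatureSeries":
        """Sub-series covering ``start``..``end`` inclusive."""
        i, j = self.index_of(start), self.index_of(end)
        if j < i:
            raise InputError("slice end precedes start")
        return TemperatureSeries(start, self.values[i : j + 1])


def load_temperature_csv(path) -> dict[str, TemperatureSeries]:
    """Read a ``trap_id,date,temp_c`` CSV into per-trap daily series.

    Dates must be ISO formatted and contiguous within each trap.
    """
    df = pd.read_csv(path)
    required = {"trap_id", "date", "temp_c"}
    if not required.issubset(df.columns):
        raise InputError(f"temperature CSV needs columns {sorted(required)}")
    out: dict[str, TemperatureSeries] = {}
    for trap, grp in df.groupby("trap_id", sort=True):
        grp = grp.sort_values("date")
        dates = pd.to_datetime(grp["date"]).dt.date.to_numpy()
        deltas = np.array([(d - dates[0]).days for d in dates])
        if not np.array_equal(deltas, np.arange(len(dates))):
            raise InputError(f"trap {trap}: temperature series has gaps or duplicates")
        out[str(trap)] = TemperatureSeries(dates[0], grp["temp_c"].to_numpy(float))
    return out


def city_mean_series(per_trap: Mapping[str, TemperatureSeries]) -> TemperatureSeries:
    """Unweighted across-trap mean, day by day (all traps must align)."""
    series = list(per_trap.values())
    if not series:
        raise InputError("no temperature series supplied")
    first = series[0]
    for s in series[1:]:
        if s.start_date != first.start_date or len(s) != len(first):
            raise InputError("per-trap series must share the same date range")
    stacked = np.vstack([s.values for s in series])
    return TemperatureSeries(first.start_date, stacked.mean(axis=0))


# ---------------------------------------------------------------------------
# Thermal-response curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BriereCurve:
    """Brière thermal performance: ``c*T*(T-T0)*sqrt(Tmax-T)`` on (T0, Tmax).

    ``scale`` multiplies the curve (used for the oviposition egg batch);
    the result is clipped to zero outside the thermal window.
    """

    c: float
    T0: float
    Tmax: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.Tmax > self.T0):
            raise ConfigurationError("Brière curve requires Tmax > T0")
        if self.c < 0 or self.scale < 0:
            raise ConfigurationError("Brière constants must be non-negative")

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        inside = (T > self.T0) & (T < self.Tmax)
        out = np.zeros_like(T)
        Ti = T[inside]
        out[inside] = self.c * Ti * (Ti - self.T0) * np.sqrt(self.Tmax - Ti)
        out *= self.scale
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SurvivalCurve:
    """Gaussian-in-temperature daily survival, bounded in [0, 1]."""

    s_max: float
    T_opt: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.s_max <= 1.0):
            raise ConfigurationError("s_max must lie in [0, 1]")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        out = self.s_max * np.exp(-(((T - self.T_opt) / self.sigma) ** 2))
        return float(out) if out.ndim == 0 else out


_CURVE_FAMILIES = {"briere": BriereCurve, "survival": SurvivalCurve}


def make_curve(family: str, **constants):
    """Build a thermal-response curve from its family id and constants."""
    try:
        cls = _CURVE_FAMILIES[family]
    except KeyError:
        raise ConfigurationError(
            f"unknown curve family {family!r}; known: {sorted(_CURVE_FAMILIES)}"
        ) from None
    return cls(**constants)


def eval_rate(curve, T):
    """Evaluate a thermal-response curve (object or ``(family, constants)``)."""
    if isinstance(curve, (BriereCurve, SurvivalCurve)):
        return curve(T)
    if isinstance(curve, Mapping):
        spec = dict(curve)
        family = spec.pop("family", None)
        return make_curve(family, **spec)(T)
    raise ConfigurationError(f"cannot interpret curve spec {curve!r}")


@dataclass(frozen=True)
class RateCurveSet:
    """The full set of thermal responses plus the female egg fraction."""

    dev_egg: BriereCurve        # egg -> larva hatching probability / day
    dev_larva: BriereCurve      # larva -> pupa development probability / day
    dev_pupa: BriereCurve       # pupa -> adult emergence probability / day
    ovi: BriereCurve            # eggs laid per adult female per day
    surv_egg: SurvivalCurve
    surv_larva: SurvivalCurve
    surv_pupa: SurvivalCurve
    surv_adult: SurvivalCurve
    sex_ratio: float = 0.5

    def daily(self, temps: np.ndarray):
        """Pre-evaluate every curve on a temperature vector.

        Development/oviposition outputs are clipped so they remain valid
        daily probabilities / per-capita rates; this is the hot path of
        calibration (rates depend on temperature only, not on alpha/K).
        """
        T = np.asarray(temps, dtype=float)
        return {
            "hatch": np.clip(self.dev_egg(T), 0.0, 1.0),
            "pupate": np.clip(self.dev_larva(T), 0.0, 1.0),
            "emerge": np.clip(self.dev_pupa(T), 0.0, 1.0),
            "ovi": np.maximum(self.ovi(T), 0.0),
            "sE": self.surv_egg(T),
            "sL": self.surv_larva(T),
            "sP": self.surv_pupa(T),
            "sA": self.surv_adult(T),
        }


def default_rates() -> RateCurveSet:
    """Default thermal-response constants.

    Development peaks near 27.5 °C (inside the favourable 23–28 °C
    window): at the optimum the Brière term ``T(T-T0)sqrt(Tmax-T)`` is
    ~1129, so ``c`` converts it to a daily probability (e.g. ``c=1.2e-4``
    gives a ~7.4-day larval stage at the optimum).  Egg survival is broad
    (drought/cold-resistant *Aedes* eggs); adult survival peaks at
    moderate temperatures so that hot summers depress abundance.
    """
    return RateCurveSet(
        dev_egg=BriereCurve(c=2.0e-4, T0=10.0, Tmax=33.0),
        dev_larva=BriereCurve(c=1.2e-4, T0=10.0, Tmax=33.0),
        dev_pupa=BriereCurve(c=3.0e-4, T0=10.0, Tmax=33.0),
        ovi=BriereCurve(c=8.0e-5, T0=10.0, Tmax=33.0, scale=60.0),
        surv_egg=SurvivalCurve(s_max=0.995, T_opt=24.0, sigma=35.0),
        surv_larva=SurvivalCurve(s_max=0.96, T_opt=25.0, sigma=11.0),
        surv_pupa=SurvivalCurve(s_max=0.96, T_opt=25.0, sigma=11.0),
        surv_adult=SurvivalCurve(s_max=0.90, T_opt=23.0, sigma=10.0),
    )


_CONFIG_FIELDS = {
    "dev_egg": ("c", "T0", "Tmax", "scale"),
    "dev_larva": ("c", "T0", "Tmax", "scale"),
    "dev_pupa": ("c", "T0", "Tmax", "scale"),
    "ovi": ("c", "T0", "Tmax", "scale"),
    "surv_egg": ("s_max", "T_opt", "sigma"),
    "surv_larva": ("s_max", "T_opt", "sigma"),
    "surv_pupa": ("s_max", "T_opt", "sigma"),
    "surv_adult": ("s_max", "T_opt", "sigma"),
}


def rates_to_config(rates: RateCurveSet) -> str:
    """Serialise a rate set to the flat ``name.constant = value`` format."""
    lines = []
    for name, keys in _CONFIG_FIELDS.items():
        curve = getattr(rates, name)
        for k in keys:
            lines.append(f"{name}.{k} = {getattr(curve, k)!r}")
    lines.append(f"sex_ratio = {rates.sex_ratio!r}")
    return "\n".join(lines) + "\n"


def rates_from_config(text: str, base: RateCurveSet | None = None) -> RateCurveSet:
    """Parse a flat key-value rate config, overriding ``base`` (defaults).

    Lines look like ``dev_larva.T0 = 10.0``; ``#`` starts a comment.
    """
    rates = base if base is not None else default_rates()
    overrides: dict[str, dict[str, float]] = {}
    sex_ratio = rates.sex_ratio
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"rate config line {lineno}: missing '='")
        key, val = (part.strip() for part in line.split("=", 1))
        try:
            value = float(val)
        except ValueError:
            raise ConfigurationError(f"rate config line {lineno}: bad number {val!r}")
        if key == "sex_ratio":
            sex_ratio = value
            continue
        if "." not in key:
            raise ConfigurationError(f"rate config line {lineno}: key {key!r} not 'curve.constant'")
        curve_name, const = key.split(".", 1)
        if curve_name not in _CONFIG_FIELDS or const not in _CONFIG_FIELDS[curve_name]:
            raise ConfigurationError(f"rate config line {lineno}: unknown key {key!r}")
        overrides.setdefault(curve_name, {})[const] = value
    new_curves = {}
    for name, consts in overrides.items():
        new_curves[name] = replace(getattr(rates, name), **consts)
    return replace(rates, sex_ratio=sex_ratio, **new_curves)


# ---------------------------------------------------------------------------
# State, parameters, trajectory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageState:
    """Continuous abundances of the four stages (all ≥ 0 and finite)."""

    E: float
    L: float
    P: float
    A: float

    def __post_init__(self) -> None:
        for name in ("E", "L", "P", "A"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not math.isfinite(v) or v < 0:
                raise InvariantError(f"stage {name} must be finite and ≥ 0, got {v}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.E, self.L, self.P, self.A)


@dataclass(frozen=True)
class ParameterSet:
    """The calibration estimand Ψ plus fixed model configuration.

    ``alpha`` is the daily capture rate (fraction of host-seeking adult
    females a trap removes per day; shared across years).  ``K_by_year``
    maps each modelled year to its carrying-capacity scaling (larvae per
    trap-coverage area).  The season is initialised from an egg pool of
    ``init_eggs`` on ``season_start`` (month, day), by default April 1.
    """

    alpha: float
    K_by_year: Mapping[int, float]
    rates: RateCurveSet = field(default_factory=default_rates)
    init_eggs: float = 5000.0
    season_start: tuple[int, int] = (4, 1)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise InvariantError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not self.K_by_year:
            raise InvariantError("K_by_year must contain at least one year")
        for year, K in self.K_by_year.items():
            if not (K > 0 and math.isfinite(K)):
                raise InvariantError(f"K[{year}] must be positive and finite")
        if self.init_eggs < 0:
            raise InvariantError("init_eggs must be ≥ 0")
        object.__setattr__(self, "K_by_year", dict(self.K_by_year))

    def K_for(self, year: int) -> float:
        try:
            return self.K_by_year[year]
        except KeyError:
            raise InputError(f"no carrying-capacity K configured for year {year}") from None

    def season_start_date(self, year: int) -> dt.date:
        return dt.date(year, *self.season_start)


@dataclass(frozen=True)
class Trajectory:
    """Daily stage abundances produced by the simulator."""

    start_date: dt.date
    E: np.ndarray
    L: np.ndarray
    P: np.ndarray
    A: np.ndarray

    def __len__(self) -> int:
        return self.A.size

    @property
    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(len(self))]

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=len(self) - 1)

    def index_of(self, day: dt.date) -> int:
        i = (day - self.start_date).days
        if i < 0 or i >= len(self):
            raise InputError(f"date {day} outside trajectory {self.start_date}..{self.end_date}")
        return i

    def state_on(self, day: dt.date) -> StageState:
        i = self.index_of(day)
        return StageState(self.E[i], self.L[i], self.P[i], self.A[i])

    def adults_on(self, days: Iterable[dt.date]) -> np.ndarray:
        return np.array([self.A[self.index_of(d)] for d in days])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "E": self.E, "L": self.L, "P": self.P, "A": self.A}
        )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _step(E, L, P, A, sE, sL, sP, sA, hatch, pupate, emerge, ovi, sex_ratio, K):
    # survival
    E = E * sE
    L = L * sL
    P = P * sP
    A = A * sA
    # density-dependent larval reduction (Beverton–Holt)
    L = L / (1.0 + L / K)
    # stage transitions
    hatched = E * hatch
    pupated = L * pupate
    emerged = P * emerge
    E -= hatched
    L += hatched - pupated
    P += pupated - emerged
    A += emerged
    # oviposition (female eggs only)
    E += A * ovi * sex_ratio
    return E, L, P, A


def step_day(s: StageState, T: float, p: ParameterSet, year: int) -> StageState:
    """Advance the population one day at temperature ``T`` (°C)."""
    K = p.K_for(year)
    r = p.rates.daily(np.array([float(T)]))
    E, L, P, A = _step(
        s.E, s.L, s.P, s.A,
        float(r["sE"][0]), float(r["sL"][0]), float(r["sP"][0]), float(r["sA"][0]),
        float(r["hatch"][0]), float(r["pupate"][0]), float(r["emerge"][0]),
        float(r["ovi"][0]), p.rates.sex_ratio, K,
    )
    return StageState(E, L, P, A)


def simulate_from_daily_rates(daily: Mapping[str, np.ndarray], K: float,
                              init_eggs: float, sex_ratio: float = 0.5) -> np.ndarray:
    """Run the daily update over pre-evaluated rates; returns a (n, 4) array.

    This is the calibration hot path: the thermal responses depend only
    on the temperature series, so they are evaluated once and reused for
    every (alpha, K) proposal.  Plain-float arithmetic keeps the
    sequential loop fast.
    """
    sE = daily["sE"].tolist(); sL = daily["sL"].tolist()
    sP = daily["sP"].tolist(); sA = daily["sA"].tolist()
    hatch = daily["hatch"].tolist(); pupate = daily["pupate"].tolist()
    emerge = daily["emerge"].tolist(); ovi = daily["ovi"].tolist()
    n = len(sE)
    out = np.empty((n, 4))
    E, L, P, A = float(init_eggs), 0.0, 0.0, 0.0
    out[0] = (E, L, P, A)
    K = float(K)
    for t in range(1, n):
        # inline of _step, scalar floats
        e = E * sE[t]; l = L * sL[t]; pp = P * sP[t]; a = A * sA[t]
        l = l / (1.0 + l / K)
        hat = e * hatch[t]; pup = l * pupate[t]; eme = pp * emerge[t]
        E = e - hat
        L = l + hat - pup
        P = pp + pup - eme
        A = a + eme
        E += A * ovi[t] * sex_ratio
        out[t] = (E, L, P, A)
    return out


def simulate_season(temps: TemperatureSeries, p: ParameterSet, year: int) -> Trajectory:
    """Deterministic daily simulation from the season start to the series end.

    The series must cover the configured season start (April 1 by
    default); the trajectory spans season start .. ``temps.end_date`` and
    begins from an egg pool of ``p.init_eggs`` with no other stages.
    """
    start = p.season_start_date(year)
    season = temps.slice(start, temps.end_date)
    daily = p.rates.daily(season.values)
    states = simulate_from_daily_rates(daily, p.K_for(year), p.init_eggs, p.rates.sex_ratio)
    return Trajectory(start, states[:, 0], states[:, 1], states[:, 2], states[:, 3])


def expected_captures(traj: Trajectory, alpha: float,
                      session_dates: Sequence[dt.date]) -> np.ndarray:
    """Model-predicted captures ``C(m) = alpha * A(t_m)`` per session.

    Captures are not removed from the population: at a ~1.5 %/day capture
    rate the feedback on the dynamics is negligible.
    """
    if alpha < 0:
        raise InvariantError("alpha must be ≥ 0")
    return alpha * traj.adults_on(session_dates)
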