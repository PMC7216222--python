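"""Site-level statistics linking captures to environment.

Yearly per-site totals Y of trapped adult females are modelled as
negative binomial counts, Y ~ NB(µ, θ) with log µ = a + bX and
Var(Y) = µ + µ²/θ, where X is a windowed land-surface-temperature mean
(spring = April–May or summer = June–August).  Associations with human
density and vegetation cover use Kendall rank correlation (tau-b, tie
corrected).  Covariates are extracted inside a circular buffer around
each trap (250 m by default): the summed population of cells whose
centers fall in the buffer, and the fraction of buffer cells in the
three non-urban land-cover classes that together define "vegetation".

The NB GLM is fitted by alternating maximisation: given θ, the log-link
regression is an IRLS GLM fit; given the fitted means, θ is updated by
univariate profile likelihood.  Wald p-values come from the final GLM
step.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import gammaln

from .popmodel import InputError, TemperatureSeries
from .spatial import GridField, buffer_mask

__all__ = [
    "LAND_COVER_CLASSES",
    "VEGETATION_CLASSES",
    "DegenerateDataError",
    "SiteYearRecord",
    "GlmFit",
    "window_mean_temperature",
    "fit_nb_glm",
    "percent_change",
    "kendall_tau",
    "buffer_cover_fraction",
    "buffer_population",
    "assemble_site_year_table",
    "results_table",
]

# Corine-style land-cover classes observed around the trap sites; the last
# three (non-urban) classes together define "vegetation cover".
LAND_COVER_CLASSES: dict[int, str] = {
    1: "discontinuous urban fabric",
    2: "industrial or commercial units",
    3: "non-irrigated arable land",
    4: "complex cultivation patterns",
    5: "land principally occupied by agriculture with significant areas of natural vegetation",
}
VEGETATION_CLASSES: frozenset[int] = frozenset({3, 4, 5})

WINDOWS = {"spring": ((4, 1), (5, 31)), "summer": ((6, 1), (8, 31))}


class DegenerateDataError(ValueError):
    """The data admit no fit (constant predictor, all-tied ranks, ...)."""


@dataclass(frozen=True)
class SiteYearRecord:
    """One trap-year: total captures plus site covariates."""

    trap_id: str
    year: int
    Y: int
    spring_lst: float
    summer_lst: float
    human_density: float
    vegetation_cover: float

    def __post_init__(self) -> None:
        if self.Y < 0 or int(self.Y) != self.Y:
            raise InputError("yearly total Y must be a non-negative integer")
        if not (0.0 <= self.vegetation_cover <= 1.0):
            raise InputError("vegetation_cover must lie in [0, 1]")


def window_mean_temperature(ts: TemperatureSeries, window: str, year: int) -> float:
    """Unweighted mean daily temperature over a named seasonal window."""
    if window not in WINDOWS:
        raise InputError(f"unknown window {window!r}; choose from {sorted(WINDOWS)}")
    (m0, d0), (m1, d1) = WINDOWS[window]
    sub = ts.slice(dt.date(year, m0, d0), dt.date(year, m1, d1))
    return float(sub.values.mean())


# ---------------------------------------------------------------------------
# Negative binomial GLM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmFit:
    """Fitted NB regression: log µ = a + bX, Var(Y) = µ + µ²/θ."""

    a: float
    b: float
    theta: float
    p_values: Mapping[str, float]
    fitted_mu: np.ndarray
    loglik: float
    converged: bool
    predictor: str

    def predict_mu(self, x) -> np.ndarray:
        return np.exp(self.a + self.b * np.asarray(x, float))


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 log-likelihood with mean µ and dispersion θ."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    return float(np.sum(
        gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    ))


def _records_to_xy(records, predictor: str) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if predictor not in df.columns:
        raise InputError(f"predictor column {predictor!r} not found")
    if "Y" not in df.columns:
        raise InputError("records need a 'Y' response column")
    y = df["Y"].to_numpy(float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise InputError("response Y must be non-negative integers")
    x = df[predictor].to_numpy(float)
    return x, y


def fit_nb_glm(records, predictor: str, max_iter: int = 50,
               tol: float = 1e-8) -> GlmFit:
    """Maximum-likelihood NB GLM of Y on one predictor (log link).

    θ is profiled: the regression step holds θ fixed (statsmodels GLM
    with a NegativeBinomial family), the dispersion step maximises the
    NB log-likelihood in θ given the fitted means; the two alternate to
    convergence.
    """
    x, y = _records_to_xy(records, predictor)
    if np.unique(x).size < 3:
        raise DegenerateDataError(
            "predictor must take at least 3 distinct values (singular fit)"
        )
    X = sm.add_constant(x)
    # moment start for theta: Var = mu + mu^2/theta
    mu0 = max(y.mean(), 1e-8)
    excess = max(y.var() - mu0, 1e-8)
    theta = float(np.clip(mu0**2 / excess, 1e-3, 1e6))
    res = None
    converged = False
    for _ in range(max_iter):
        fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
        res = sm.GLM(y, X, family=fam).fit()
        mu = res.fittedvalues

        def neg_profile(log_theta: float) -> float:
            return -nb_loglik(y, mu, math.exp(log_theta))

        opt = optimize.minimize_scalar(
            neg_profile, bounds=(math.log(1e-3), math.log(1e6)), method="bounded"
        )
        new_theta = float(math.exp(opt.x))
        if abs(math.log(new_theta) - math.log(theta)) < tol:
            theta = new_theta
            converged = True
            break
        theta = new_theta
    a, b = (float(v) for v in res.params)
    pvals = {"intercept": float(res.pvalues[0]), "slope": float(res.pvalues[1])}
    return GlmFit(
        a=a, b=b, theta=theta, p_values=pvals,
        fitted_mu=np.asarray(res.fittedvalues, float),
        loglik=nb_loglik(y, res.fittedvalues, theta),
        converged=converged, predictor=predictor,
    )


def percent_change(b: float, delta_T: float) -> float:
    """Percent decrease in expected captures for a ΔT °C shift.

    With log µ = a + bX, a shift of ΔT multiplies µ by exp(b ΔT); the
    result 100·(1 − exp(b ΔT)) is positive for a decrease.
    """
    return 100.0 * (1.0 - math.exp(b * delta_T))


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

def kendall_tau(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """Kendall tau-b with tie correction and its two-sided p-value.

    The p-value is exact (pair-count enumeration) for small untied
    samples and a tie-adjusted normal approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("kendall_tau needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("tau is undefined for an all-constant input")
    res = stats.kendalltau(x, y, variant="b", method="auto")
    return {"tau": float(res.statistic), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# Buffer covariate extraction
# ---------------------------------------------------------------------------

def buffer_cover_fraction(grid: GridField, center: tuple[float, float],
                          radius: float = 250.0,
                          classes: frozenset[int] | set[int] = VEGETATION_CLASSES,
                          ) -> float:
    """Fraction of buffer cells whose land-cover class is in ``classes``.

    Cell membership uses the cell-center-in-circle rule.
    """
    mask = buffer_mask(grid, center, radius)
    in_buffer = grid.values[mask]
    matches = np.isin(in_buffer, list(classes)) & np.isfinite(in_buffer)
    return float(matches.sum() / in_buffer.size)


def buffer_population(grid: GridField, center: tuple[float, float],
                      radius: float = 250.0) -> float:
    """Sum of raster values over cells whose centers fall in the buffer."""
    mask = buffer_mask(grid, center, radius)
    return float(np.nansum(grid.values[mask]))


# ---------------------------------------------------------------------------
# Assembling the analysis table
# ---------------------------------------------------------------------------

def assemble_site_year_table(per_trap_captures: pd.DataFrame,
                             temps: Mapping[str, TemperatureSeries] | Mapping[int, Mapping[str, TemperatureSeries]],
                             density: GridField,
                             landcover: GridField,
                             coords: Mapping[str, tuple[float, float]],
                             years: Sequence[int],
                             radius: float = 250.0) -> pd.DataFrame:
    """Build the trap-year analysis table from raw inputs.

    ``temps`` maps year -> trap -> TemperatureSeries (or trap -> series
    valid for all years).  Returns one row per trap and year with the
    yearly total Y, windowed LST means, buffer human density and
    vegetation cover.
    """
    df = per_trap_captures.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["year"] = [d.year for d in df["date"]]
    rows = []
    for trap, (cx, cy) in coords.items():
        hd = buffer_population(density, (cx, cy), radius)
        veg = buffer_cover_fraction(landcover, (cx, cy), radius)
        for year in years:
            t_map = temps.get(year, temps) if isinstance(next(iter(temps)), int) else temps
            ts = t_map[trap]
            sel = (df["trap_id"].astype(str) == str(trap)) & (df["year"] == year)
            rows.append({
                "trap_id": str(trap),
                "year": int(year),
                "Y": int(df.loc[sel, "count"].sum()),
                "spring_lst": window_mean_temperature(ts, "spring", year),
                "summer_lst": window_mean_temperature(ts, "summer", year),
                "human_density": hd,
                "vegetation_cover": veg,
            })
    return pd.DataFrame(rows)


def results_table(site_table: pd.DataFrame,
                  correlation_aggregation: str = "total") -> pd.DataFrame:
    """Run the standard battery of site-level tests.

    GLMs of Y on the spring and summer LST windows are fitted on the
    pooled trap-year records; Kendall correlations of captures with
    human density and vegetation cover use either per-trap totals
    pooled over all years (``"total"``) or trap-year records
    (``"yearly"``).  Returns a tidy table (term, estimate, p-value).
    """
    rows = []
    for window in ("spring_lst", "summer_lst"):
        fit = fit_nb_glm(site_table, window)
        label = "spring" if window.startswith("spring") else "summer"
        rows.append({"variable": f"average {label} temperature",
                     "test": "Negative Binomial GLM", "term": "intercept",
                     "estimate": fit.a, "p_value": fit.p_values["intercept"]})
        rows.append({"variable": f"average {label} temperature",
                     "test": "Negative Binomial GLM", "term": "slope",
                     "estimate": fit.b, "p_value": fit.p_values["slope"]})
    if correlation_aggregation == "total":
        agg = site_table.groupby("trap_id").agg(
            Y=("Y", "sum"),
            human_density=("human_density", "first"),
            vegetation_cover=("vegetation_cover", "first"),
        )
    elif correlation_aggregation == "yearly":
        agg = site_table
    else:
        raise InputError("correlation_aggregation must be 'total' or 'yearly'")
    for var, label in (("human_density", "human population"),
                       ("vegetation_cover", "vegetation cover")):
        kt = kendall_tau(agg[var].to_numpy(), agg["Y"].to_numpy())
        rows.append({"variable": label, "test": "Kendall correlation test",
                     "term": "tau", "estimate": kt["tau"],
                     "p_value": kt["p_value"]})
    return pd.DataFrame(rows)
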