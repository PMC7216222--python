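"""City-scale abundance mapping.

A trap is assumed to sample, on average, a circular coverage area
Ω = π r² around it, with r the species' mean daily flight range (150 m
by default).  The population model yields M(t), the adult-female
abundance per Ω; multiplying a seasonal mean of M(t) by A/Ω — A being
the area of the mapped region — gives a city-wide total, which is then
redistributed over the 100 m grid by universal kriging of per-trap
density indices with human density as the linear drift, and finally
rescaled so the hectare-integrated map reproduces the city total
exactly (mass conservation).

Rasters are read and written as ESRI ASCII grids; planar coordinates in
metres are assumed throughout (no projection handling).
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .popmodel import InputError, Trajectory

__all__ = [
    "GridField",
    "MapSpec",
    "Variogram",
    "KrigingError",
    "read_ascii_grid",
    "write_ascii_grid",
    "trap_coverage_area",
    "city_total",
    "seasonal_mean_density",
    "empirical_variogram",
    "fit_variogram",
    "universal_krige",
    "krige_at_points",
    "seasonal_abundance_map",
    "rescale_to_total",
]


class KrigingError(RuntimeError):
    """The kriging system could not be solved."""


# ---------------------------------------------------------------------------
# Raster container and ESRI ASCII I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridField:
    """A georeferenced raster: row 0 is the northernmost row (ESRI order).

    ``values`` may contain NaN for missing cells; ``units`` is a free
    label (e.g. "persons/cell" or "females/ha").
    """

    xll: float
    yll: float
    cellsize: float
    values: np.ndarray
    units: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.cellsize <= 0:
            raise InputError("cellsize must be positive")
        if vals.ndim != 2 or vals.size == 0:
            raise InputError("grid values must be a non-empty 2-d array")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def area(self) -> float:
        """Total grid extent in m² (planar)."""
        return self.n_rows * self.n_cols * self.cellsize**2

    @property
    def cell_area_ha(self) -> float:
        return self.cellsize**2 / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of every cell center, grid-shaped."""
        cols = self.xll + (np.arange(self.n_cols) + 0.5) * self.cellsize
        rows = self.yll + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cellsize
        return np.meshgrid(cols, rows)

    def index_at(self, x: float, y: float) -> tuple[int, int]:
        col = int(math.floor((x - self.xll) / self.cellsize))
        row = self.n_rows - 1 - int(math.floor((y - self.yll) / self.cellsize))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InputError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_at(x, y)
        return float(self.values[r, c])

    def values_at(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return np.array([self.value_at(x, y) for x, y in zip(xs, ys)])

    def with_values(self, values: np.ndarray, units: str | None = None) -> "GridField":
        return replace(self, values=np.asarray(values, float),
                       units=self.units if units is None else units)


def read_ascii_grid(path, units: str = "") -> GridField:
    """Read an ESRI ASCII grid (.asc). NODATA cells become NaN."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise InputError(f"ASCII grid missing header field {req}")
    values = np.array([v for row in rows for v in row], dtype=float)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    if values.size != nr * nc:
        raise InputError(f"ASCII grid: expected {nr * nc} cells, found {values.size}")
    values = values.reshape(nr, nc)
    nodata = header.get("nodata_value", -9999.0)
    values[values == nodata] = np.nan
    return GridField(header["xllcorner"], header["yllcorner"], header["cellsize"],
                     values, units=units, nodata=nodata)


def write_ascii_grid(grid: GridField, path) -> None:
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def buffer_mask(grid: GridField, center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of cells whose centers lie inside the circular buffer."""
    if radius <= 0:
        raise InputError("buffer radius must be positive")
    X, Y = grid.cell_centers()
    mask = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
    if not mask.any():
        raise InputError("buffer does not cover any grid cell center")
    return mask


# ---------------------------------------------------------------------------
# Trap coverage and city totals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MapSpec:
    """Geometry of the abundance mapping.

    ``r`` is the mean daily flight range in metres (default 150 m) and
    fixes the trap coverage Ω = π r²; ``A`` is the mapped-region area in
    m²; ``season`` is the (inclusive) month-day window over which daily
    adult abundance is averaged, June 1 – September 30 by default.
    """

    r: float = 150.0
    A: float | None = None
    season: tuple[tuple[int, int], tuple[int, int]] = ((6, 1), (9, 30))

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise InputError("flight range r must be positive")
        if self.A is not None and self.A < self.omega:
            raise InputError("study area A must be at least the trap coverage Ω")

    @property
    def omega(self) -> float:
        return math.pi * self.r**2


def trap_coverage_area(r: float) -> float:
    """Trap coverage Ω = π r² (m²) for daily flight range r (m)."""
    if r <= 0:
        raise InputError("flight range r must be positive")
    return math.pi * r**2


def city_total(M_t: float, spec: MapSpec) -> float:
    """Scale per-Ω abundance to the whole region: M(t) · A / Ω."""
    if M_t < 0:
        raise InputError("abundance must be ≥ 0")
    if spec.A is None:
        raise InputError("MapSpec.A (study-area size) is not set")
    return M_t * spec.A / spec.omega


def seasonal_mean_density(traj: Trajectory, spec: MapSpec, year: int) -> float:
    """Mean daily adult abundance per Ω over the mapping season."""
    start = dt.date(year, *spec.season[0])
    end = dt.date(year, *spec.season[1])
    i, j = traj.index_of(start), traj.index_of(end)
    return float(traj.A[i : j + 1].mean())


# ---------------------------------------------------------------------------
# Variograms and universal kriging
# ---------------------------------------------------------------------------

def _gamma(model: str, h: np.ndarray, nugget: float, sill: float, rng: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    out = np.where(h > 0, nugget, 0.0)
    hp = np.maximum(h, 0.0)
    if model == "exponential":
        out = out + sill * (1.0 - np.exp(-3.0 * hp / rng))
    elif model == "gaussian":
        out = out + sill * (1.0 - np.exp(-3.0 * (hp / rng) ** 2))
    elif model == "spherical":
        ratio = np.minimum(hp / rng, 1.0)
        out = out + sill * (1.5 * ratio - 0.5 * ratio**3)
    else:
        raise InputError(f"unknown variogram model {model!r}")
    return np.where(h > 0, out, 0.0)


@dataclass(frozen=True)
class Variogram:
    model: str = "exponential"
    nugget: float = 0.0
    sill: float = 1.0
    range_: float = 1.0

    def __call__(self, h) -> np.ndarray:
        return _gamma(self.model, h, self.nugget, self.sill, self.range_)


def empirical_variogram(x: np.ndarray, y: np.ndarray, values: np.ndarray,
                        n_bins: int = 8) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram (bin centers, semivariance, pair counts)."""
    x, y, values = (np.asarray(a, float) for a in (x, y, values))
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    dist = np.sqrt(dx**2 + dy**2)
    semi = 0.5 * (values[:, None] - values[None, :]) ** 2
    iu = np.triu_indices(len(x), k=1)
    d, s = dist[iu], semi[iu]
    hmax = d.max()
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (d > lo) & (d <= hi)
        if sel.sum() == 0:
            continue
        centers.append(d[sel].mean())
        gammas.append(s[sel].mean())
        counts.append(int(sel.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(x, y, values, nugget: float = 0.0) -> Variogram:
    """Weighted-least-squares fit among exponential/spherical/Gaussian models.

    Falls back to an exponential with range = half the maximum pairwise
    distance when the empirical variogram is unusable.
    """
    x, y, values = (np.asarray(a, float) for a in (x, y, values))
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    hmax = float(np.sqrt(dx**2 + dy**2).max())
    fallback = Variogram("exponential", nugget, max(float(np.var(values)), 1e-12),
                         max(hmax / 2.0, 1e-9))
    h, g, w = empirical_variogram(x, y, values)
    if h.size < 3 or np.all(g <= 0):
        return fallback
    best, best_sse = None, math.inf
    sill0 = max(float(np.var(values)), 1e-12)
    for model in ("exponential", "spherical", "gaussian"):
        for rng0 in (hmax / 4, hmax / 2, hmax):
            for sill in (0.5 * sill0, sill0, 2.0 * sill0):
                sse = float(np.sum(w * (_gamma(model, h, nugget, sill, rng0) - g) ** 2))
                if sse < best_sse:
                    best_sse = sse
                    best = Variogram(model, nugget, sill, rng0)
    return best if best is not None else fallback


def _solve_kriging(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve the kriging system, rejecting (near-)singular matrices.

    LAPACK does not reliably flag exactly duplicated points as singular,
    so the conditioning is checked explicitly.
    """
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise KrigingError(
            f"singular kriging system (condition number {cond:.3g}); "
            "check for duplicated trap locations"
        )
    try:
        return np.linalg.solve(A, B)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cond check first
        raise KrigingError(f"singular kriging system: {exc}") from exc


def _drift_at(drift: GridField | None, xs, ys) -> np.ndarray:
    if drift is None:
        return np.zeros(len(xs))
    return drift.values_at(np.asarray(xs, float), np.asarray(ys, float))


def universal_krige(x: Sequence[float], y: Sequence[float], values: Sequence[float],
                    drift: GridField | None,
                    target: GridField | None = None,
                    variogram: Variogram | None = None,
                    clip_negative: bool = True) -> GridField:
    """Universal kriging of point values onto a grid, with a linear drift.

    The drift functions are [1, d(x)] where d is the drift raster
    (human density); with ``drift=None`` this reduces to ordinary
    kriging.  The variogram is auto-fitted to the OLS drift residuals
    unless supplied.  With nugget 0 the predictor interpolates the data
    exactly.  Negative predictions are clipped to zero by default.
    """
    x = np.asarray(x, float); y = np.asarray(y, float)
    values = np.asarray(values, float)
    if x.size < 4:
        raise InputError("universal kriging needs at least 4 points")
    if target is None:
        if drift is None:
            raise InputError("need a target grid or a drift raster")
        target = drift
    if np.ptp(values) == 0:
        warnings.warn("all point values equal; returning a constant field",
                      stacklevel=2)
        return target.with_values(np.full((target.n_rows, target.n_cols), values[0]))

    f_pts = _drift_at(drift, x, y)
    # variogram of drift residuals (OLS detrend)
    F = np.column_stack([np.ones_like(x), f_pts])
    beta, *_ = np.linalg.lstsq(F, values, rcond=None)
    resid = values - F @ beta
    vg = variogram if variogram is not None else fit_variogram(x, y, resid)

    n = x.size
    dists = np.sqrt((x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2)
    n_drift = 2 if drift is not None else 1
    A = np.zeros((n + n_drift, n + n_drift))
    A[:n, :n] = vg(dists)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    if drift is not None:
        A[:n, n + 1] = f_pts
        A[n + 1, :n] = f_pts

    X, Y = target.cell_centers()
    gx, gy = X.ravel(), Y.ravel()
    d0 = np.sqrt((gx[:, None] - x[None, :]) ** 2 + (gy[:, None] - y[None, :]) ** 2)
    B = np.zeros((n + n_drift, gx.size))
    B[:n] = vg(d0).T
    B[n] = 1.0
    if drift is not None:
        fd = drift.values
        if drift is target:
            B[n + 1] = fd.ravel()
        else:
            B[n + 1] = _drift_at(drift, gx, gy)
    lam = _solve_kriging(A, B)
    pred = values @ lam[:n]
    if clip_negative:
        pred = np.maximum(pred, 0.0)
    return target.with_values(pred.reshape(target.n_rows, target.n_cols))


def krige_at_points(x, y, values, drift: GridField | None,
                    targets_xy: np.ndarray,
                    variogram: Variogram | None = None,
                    clip_negative: bool = False) -> np.ndarray:
    """Universal-kriging predictions at arbitrary coordinates (same system
    as :func:`universal_krige`; used for exactness checks and point targets)."""
    targets_xy = np.asarray(targets_xy, float)
    # reuse the grid path by building a 1-cell-per-target pseudo grid is
    # awkward; duplicate the small solve instead
    x = np.asarray(x, float); y = np.asarray(y, float)
    values = np.asarray(values, float)
    if x.size < 4:
        raise InputError("universal kriging needs at least 4 points")
    f_pts = _drift_at(drift, x, y)
    F = np.column_stack([np.ones_like(x), f_pts])
    beta, *_ = np.linalg.lstsq(F, values, rcond=None)
    vg = variogram if variogram is not None else fit_variogram(x, y, values - F @ beta)
    n = x.size
    n_drift = 2 if drift is not None else 1
    dists = np.sqrt((x[:, None] - x[None, :]) ** 2 + (y[:, None] - y[None, :]) ** 2)
    A = np.zeros((n + n_drift, n + n_drift))
    A[:n, :n] = vg(dists)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    if drift is not None:
        A[:n, n + 1] = f_pts
        A[n + 1, :n] = f_pts
    tx, ty = targets_xy[:, 0], targets_xy[:, 1]
    d0 = np.sqrt((tx[:, None] - x[None, :]) ** 2 + (ty[:, None] - y[None, :]) ** 2)
    B = np.zeros((n + n_drift, tx.size))
    B[:n] = vg(d0).T
    B[n] = 1.0
    if drift is not None:
        B[n + 1] = _drift_at(drift, tx, ty)
    lam = _solve_kriging(A, B)
    pred = values @ lam[:n]
    return np.maximum(pred, 0.0) if clip_negative else pred


def seasonal_abundance_map(trap_xy: Mapping[str, tuple[float, float]],
                           trap_mean_captures: Mapping[str, float],
                           alpha: float,
                           traj: Trajectory,
                           year: int,
                           density: GridField,
                           spec: MapSpec | None = None) -> GridField:
    """Kriged seasonal abundance map (adult females per hectare).

    Per-trap seasonal mean captures are converted to local densities
    (captures / alpha / Ω, per ha) and kriged over the human-density
    raster (linear drift); the map is then rescaled so its
    hectare-integrated mass equals the city total A/Ω · M̄, with M̄ the
    seasonal mean of the simulated adult abundance per Ω.
    """
    spec = spec or MapSpec()
    if spec.A is None:
        spec = replace(spec, A=density.area)
    if alpha <= 0:
        raise InputError("alpha must be positive to convert captures to densities")
    traps = sorted(trap_xy)
    xs = np.array([trap_xy[t][0] for t in traps])
    ys = np.array([trap_xy[t][1] for t in traps])
    omega_ha = spec.omega / 1e4
    vals = np.array([trap_mean_captures[t] / alpha / omega_ha for t in traps])
    M_bar = seasonal_mean_density(traj, spec, year)
    total = city_total(M_bar, spec)
    kriged = universal_krige(xs, ys, vals, drift=density, target=density)
    out = rescale_to_total(kriged, total)
    return replace(out, units="females/ha")


def rescale_to_total(grid: GridField, total: float) -> GridField:
    """Rescale a per-hectare density map so it integrates to ``total``.

    The hectare-integrated mass Σ(cell value × cell area in ha) is made
    equal to ``total`` by a single multiplicative constant; the spatial
    shape is preserved exactly.
    """
    finite = np.isfinite(grid.values)
    mass = float(np.nansum(grid.values[finite])) * grid.cell_area_ha
    if mass <= 0:
        raise InputError("cannot rescale a zero-mass field")
    return grid.with_values(grid.values * (total / mass))
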