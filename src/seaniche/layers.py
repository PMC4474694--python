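"""Derivation and screening of the environmental predictor layers.

The predictor set is the classic coastal-cetacean quintet: depth, seabed
slope, distance to the shoreline, and per-season sea-surface-temperature
mean and temporal standard deviation (SST, SST-SD), all on one shared grid.

Depth is interpolated from scattered bathymetric soundings by ordinary
kriging (exponential variogram fitted by weighted least squares) or, as a
configurable fallback, inverse-distance weighting.  Slope at a cell is the
maximum slope toward any of its eight neighbours.  Distance to shore is the
Euclidean distance from a marine cell centre to the nearest land cell
centre.  A correlation screen flags predictor pairs whose coefficient
exceeds a threshold (default 0.7) before modelling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.linalg import lu_factor, lu_solve

from .grids import EnvStack, GridSpec, Raster
from .occurrences import DEFAULT_SEASONS, season_of_date

__all__ = [
    "interpolate_depth", "slope_from_depth", "distance_to_shore",
    "seasonal_sst_stats", "correlation_screen", "exponential_variogram",
]

# offsets and centre-to-centre distances (in cell units) of the 8 neighbours
_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]


def exponential_variogram(h, nugget, sill, rng):
    """Semivariance gamma(h) = nugget + sill * (1 - exp(-3h / range))."""
    return nugget + sill * (1.0 - np.exp(-3.0 * h / max(rng, 1e-12)))


def _fit_variogram(pts: np.ndarray, z: np.ndarray, n_bins: int = 15):
    """Fit an exponential variogram model to the empirical semivariogram.

    Bins pairwise semivariances up to half the maximum separation and fits
    (nugget, sill, range) by least squares weighted by sqrt(pair counts).
    """
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    g = 0.5 * (z[:, None] - z[None, :]) ** 2
    iu = np.triu_indices(len(z), k=1)
    d, g = d[iu], g[iu]
    dmax = d.max() / 2.0
    edges = np.linspace(0, dmax, n_bins + 1)
    idx = np.digitize(d, edges) - 1
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        gamma_hat = np.bincount(idx[keep], weights=g[keep], minlength=n_bins) / counts
        h_mid = np.bincount(idx[keep], weights=d[keep], minlength=n_bins) / counts
    ok = counts > 0
    h_mid, gamma_hat, counts = h_mid[ok], gamma_hat[ok], counts[ok]

    var_z = float(np.var(z))
    x0 = np.array([1e-6, max(var_z, 1e-6), dmax / 2.0])

    def resid(p):
        return np.sqrt(counts) * (exponential_variogram(h_mid, *p) - gamma_hat)

    sol = optimize.least_squares(
        resid, x0, bounds=([0, 1e-12, 1e-6], [np.inf, np.inf, np.inf]))
    return tuple(sol.x)


def _dedupe_points(points: np.ndarray) -> np.ndarray:
    """Average depths of points sharing identical coordinates."""
    df = pd.DataFrame(points, columns=["x", "y", "z"])
    return df.groupby(["x", "y"], as_index=False)["z"].mean().to_numpy()


def interpolate_depth(points, grid: GridSpec, method: str = "kriging",
                      max_points: int = 600, idw_power: float = 2.0,
                      idw_k: int = 12, variogram_params=None) -> Raster:
    """Interpolate scattered (x, y, depth) soundings onto every marine cell.

    Parameters
    ----------
    points : array-like, shape (n, 3)
        Columns x, y (planar metres) and depth (metres, >= 0).
    method : {"kriging", "idw"}
        Ordinary kriging (default) or inverse-distance weighting.
    max_points : int
        Kriging uses at most this many soundings (evenly thinned) to keep
        the linear system tractable.
    variogram_params : tuple, optional
        (nugget, sill, range) to use instead of fitting.

    Both methods interpolate exactly at cells that contain a sounding and
    return finite values on every marine cell (extrapolation is allowed).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of x, y, depth")
    points = _dedupe_points(points)
    if len(points) < 3:
        raise ValueError("need at least 3 distinct bathymetric points")
    if np.any(points[:, 2] < 0):
        raise ValueError("depths must be non-negative")
    v = points[:, :2] - points[0, :2]
    cross = v[1, 0] * v[:, 1] - v[1, 1] * v[:, 0]
    if np.allclose(cross, 0.0):
        raise ValueError("bathymetric points are collinear")
    inside_x = (points[:, 0] >= grid.origin_x) & (
        points[:, 0] <= grid.origin_x + grid.n_cols * grid.cell_size)
    inside_y = (points[:, 1] <= grid.origin_y) & (
        points[:, 1] >= grid.origin_y - grid.n_rows * grid.cell_size)
    if not np.any(inside_x & inside_y):
        raise ValueError("all bathymetric points fall outside the grid")

    xg, yg = grid.cell_centers()
    tx = xg[grid.mask]
    ty = yg[grid.mask]
    z = points[:, 2]

    if np.ptp(z) < 1e-12:  # constant field: both methods return the constant
        vals = np.full(grid.shape, z[0])
        return Raster(grid, vals, name="depth", units="m")

    if method == "idw":
        pred = _idw(points, tx, ty, power=idw_power, k=idw_k)
    elif method == "kriging":
        if len(points) > max_points:
            sel = np.linspace(0, len(points) - 1, max_points).astype(int)
            points = points[np.unique(sel)]
            z = points[:, 2]
        if variogram_params is None:
            variogram_params = _fit_variogram(points[:, :2], z)
        pred = _ordinary_kriging(points, tx, ty, variogram_params)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")

    vals = np.full(grid.shape, np.nan)
    vals[grid.mask] = np.maximum(pred, 0.0)
    return Raster(grid, vals, name="depth", units="m")


def _idw(points, tx, ty, power=2.0, k=12):
    from scipy.spatial import cKDTree
    tree = cKDTree(points[:, :2])
    k = min(k, len(points))
    dist, idx = tree.query(np.column_stack([tx, ty]), k=k)
    dist = np.atleast_2d(dist.T).T
    idx = np.atleast_2d(idx.T).T
    exact = dist[:, 0] < 1e-9
    with np.errstate(divide="ignore"):
        w = 1.0 / dist ** power
    w[exact] = 0.0
    w[exact, 0] = 1.0
    pred = (w * points[idx, 2]).sum(1) / w.sum(1)
    return pred


def _ordinary_kriging(points, tx, ty, variogram_params):
    pts = points[:, :2]
    z = points[:, 2]
    n = len(pts)
    h = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = exponential_variogram(h, *variogram_params)
    np.fill_diagonal(K[:n, :n], 0.0)  # exact interpolation at soundings
    K[n, :n] = 1.0
    K[:n, n] = 1.0
    try:
        lu = lu_factor(K)
    except Exception:  # singular geometry: fall back to IDW
        return _idw(points, tx, ty)
    targets = np.column_stack([tx, ty])
    # solve in chunks to bound memory
    pred = np.empty(len(targets))
    chunk = 4096
    for start in range(0, len(targets), chunk):
        t = targets[start:start + chunk]
        ht = np.sqrt(((t[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        gam = exponential_variogram(ht, *variogram_params)
        gam[ht < 1e-9] = 0.0  # coincident sounding: exact interpolation
        rhs = np.empty((n + 1, len(t)))
        rhs[:n] = gam.T
        rhs[n] = 1.0
        w = lu_solve(lu, rhs)
        pred[start:start + chunk] = w[:n].T @ z
    return pred


def slope_from_depth(depth: Raster) -> Raster:
    """Maximum slope (degrees) toward any of the eight neighbouring cells.

    For each valid cell, slope = max over valid neighbours of
    atan(|z_n - z| / d) with d = cell_size for rook neighbours and
    cell_size * sqrt(2) for diagonal neighbours.  Neighbours under the land
    mask are ignored; a cell with no valid neighbour becomes NoData.
    """
    g = depth.grid
    z = depth.values
    best = np.full(g.shape, -np.inf)
    any_neighbor = np.zeros(g.shape, dtype=bool)
    for dr, dc in _NEIGHBOR_OFFSETS:
        zn = np.full(g.shape, np.nan)
        src = (slice(max(dr, 0), g.n_rows + min(dr, 0)),
               slice(max(dc, 0), g.n_cols + min(dc, 0)))
        dst = (slice(max(-dr, 0), g.n_rows + min(-dr, 0)),
               slice(max(-dc, 0), g.n_cols + min(-dc, 0)))
        zn[dst] = z[src]
        d = g.cell_size * (np.sqrt(2.0) if dr != 0 and dc != 0 else 1.0)
        with np.errstate(invalid="ignore"):
            s = np.degrees(np.arctan(np.abs(zn - z) / d))
        ok = np.isfinite(s)
        best = np.where(ok & (s > best), s, best)
        any_neighbor |= ok
    out_mask = g.mask & any_neighbor
    vals = np.where(out_mask, best, np.nan)
    return Raster(g.with_mask(out_mask), vals, name="slope", units="deg")


def distance_to_shore(grid: GridSpec) -> Raster:
    """Euclidean distance (m) from each marine cell centre to the nearest
    land cell centre."""
    if grid.mask.all():
        raise ValueError("mask contains no land cells: no shoreline to measure from")
    if not grid.mask.any():
        raise ValueError("mask contains no marine cells")
    dist = ndimage.distance_transform_edt(grid.mask, sampling=grid.cell_size)
    vals = np.where(grid.mask, dist, np.nan)
    return Raster(grid, vals, name="dist_shore", units="m")


def seasonal_sst_stats(sst_series, seasons: dict = DEFAULT_SEASONS
                       ) -> dict[str, tuple[Raster, Raster]]:
    """Per-season, per-cell mean and sample SD (n-1) of a dated SST stack.

    Parameters
    ----------
    sst_series : list of (date, Raster)
        Dated SST snapshots; dates may be datetime.date or ISO strings.
    seasons : mapping season name -> set of months

    Returns ``{season: (mean_raster, sd_raster)}``.  A season with fewer
    than two dates has an undefined SD and is rejected.
    """
    by_season: dict[str, list[Raster]] = {s: [] for s in seasons}
    for date, raster in sst_series:
        by_season[season_of_date(date, seasons)].append(raster)
    out = {}
    for season, rasters in by_season.items():
        if len(rasters) < 2:
            raise ValueError(
                f"season {season!r} has {len(rasters)} date(s); "
                "at least 2 are needed for a temporal SD")
        grid = rasters[0].grid
        cube = np.stack([r.values for r in rasters])
        mean = cube.mean(axis=0)
        sd = cube.std(axis=0, ddof=1)
        out[season] = (
            Raster(grid, mean, name="sst", units="degC"),
            Raster(grid, sd, name="sst_sd", units="degC"),
        )
    return out


def correlation_screen(stack: EnvStack, threshold: float = 0.7,
                       method: str = "pearson", cells: np.ndarray | None = None):
    """Pairwise correlations among predictor layers, with flagged pairs.

    Parameters
    ----------
    stack : EnvStack
    threshold : float
        A pair is flagged as highly correlated iff |r| > threshold.
    method : {"pearson", "spearman"}
    cells : boolean array over the grid, optional
        Evaluation domain; defaults to all jointly valid cells.

    Returns (matrix, flagged) where matrix is a DataFrame with unit diagonal
    and flagged is a list of (name_a, name_b, r).  A constant layer has
    undefined correlations, reported as NaN with a warning.
    """
    X = stack.covariate_matrix()
    if cells is not None:
        X = X[np.asarray(cells, bool)[stack.grid.mask]]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 common valid cells")
    names = stack.names
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = X.std(axis=0)
    const = sd < 1e-15
    if const.any():
        warnings.warn(
            f"constant layer(s) {[n for n, c in zip(names, const) if c]}: "
            "correlations undefined (NaN)")
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R[const, :] = np.nan
    R[:, const] = np.nan
    np.fill_diagonal(R, 1.0)
    matrix = pd.DataFrame(R, index=names, columns=names)
    flagged = [
        (names[i], names[j], float(R[i, j]))
        for i in range(len(names)) for j in range(i + 1, len(names))
        if np.isfinite(R[i, j]) and abs(R[i, j]) > threshold
    ]
    return matrix, flagged
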