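"""Spatial isotope gradients: correlations, variograms, ordinary kriging,
surface differencing and bootstrap guild ensembles.

The spatial sample unit is one (lon, lat, permil) triple per individual —
its time-integrated weighted mean foraging location paired with its plasma
value. Surfaces are estimated by ordinary kriging with an automatically
selected variogram (spherical / exponential / Gaussian, weighted least
squares on the binned empirical semivariance) inside a convex-hull-plus-
buffer mask around the locations. Distances are isotropic geographic
degrees; study extents are modest enough in longitude compression for this
to be a documented approximation (a projected-coordinate hook exists via
pre-projected inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint
from sklearn.base import BaseEstimator

from .errors import (DegenerateHullError, InsufficientDataError,
                     InsufficientIndividualsError, NoOverlapError,
                     SingularKrigingError, UndefinedCorrelationError)
from .grids import GridSpec

log = logging.getLogger(__name__)

VARIOGRAM_MODELS = ("spherical", "exponential", "gaussian")


# ------------------------------------------------------------- correlations

@dataclass
class RegressionResult:
    """Pearson correlation plus the OLS line on the same pairs."""

    r: float
    p: float
    slope: float
    intercept: float
    predictor: str
    n: int


def correlate(values, predictor_values, predictor: str = "lat") -> RegressionResult:
    """Pearson R (two-sided t test) and OLS slope/intercept of value on predictor."""
    x = np.asarray(predictor_values, float)
    y = np.asarray(values, float)
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in predictor or response")
    r, p = stats.pearsonr(x, y)
    ols = stats.linregress(x, y)
    return RegressionResult(float(r), float(p), float(ols.slope),
                            float(ols.intercept), predictor, len(x))


# --------------------------------------------------------------- variograms

@dataclass
class Variogram:
    """Fitted semivariogram: gamma(h) = nugget + psill * f(h / range)."""

    model: str
    nugget: float
    psill: float
    range_: float
    bins: pd.DataFrame = field(default_factory=pd.DataFrame)  # lag, gamma, count

    def gamma(self, h):
        h = np.asarray(h, float)
        if self.model == "nugget":
            return np.where(h > 0, self.nugget, 0.0)
        a = self.range_
        if self.model == "spherical":
            hr = np.clip(h / a, 0.0, 1.0)
            f = 1.5 * hr - 0.5 * hr ** 3
        elif self.model == "exponential":
            f = 1.0 - np.exp(-h / a)
        elif self.model == "gaussian":
            f = 1.0 - np.exp(-((h / a) ** 2))
        else:  # pragma: no cover
            raise ValueError(self.model)
        return np.where(h > 0, self.nugget + self.psill * f, 0.0)

    @property
    def total_sill(self) -> float:
        return self.nugget + self.psill

    def covariance(self, h):
        """C(h) = total sill - gamma(h); C(0) = total sill (micro-scale
        nugget convention, so kriging honours data at sample points)."""
        return self.total_sill - self.gamma(h)


def empirical_variogram(coords: np.ndarray, values: np.ndarray,
                        n_bins: int = 12,
                        max_lag_fraction: float = 2.0 / 3.0) -> pd.DataFrame:
    """Binned semivariance: equal-width lag bins up to a fraction of the
    maximum pairwise distance."""
    d = pdist(coords)
    g = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    max_lag = max_lag_fraction * d.max()
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        rows.append({"lag": d[m].mean(), "gamma": g[m].mean(),
                     "count": int(m.sum())})
    return pd.DataFrame(rows)


def fit_variogram(coords, values, n_bins: int = 12,
                  max_lag_fraction: float = 2.0 / 3.0) -> Variogram:
    """Pick the best of spherical/exponential/Gaussian by weighted SSE.

    Each candidate is fitted to the empirical bins by least squares with
    pair-count weights; fewer than 3 non-empty bins falls back to a
    pure-nugget model (logged).
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if len(values) < 5:
        raise InsufficientDataError("kriging needs >= 5 samples")
    emp = empirical_variogram(coords, values, n_bins, max_lag_fraction)
    if len(emp) < 3:
        var = float(values.var(ddof=1))
        log.warning("variogram undersampled (%d bins); pure nugget", len(emp))
        return Variogram("nugget", var, 0.0, 1.0, emp)
    lag = emp["lag"].to_numpy()
    gam = emp["gamma"].to_numpy()
    w = np.sqrt(emp["count"].to_numpy(float))
    var = max(float(values.var(ddof=1)), 1e-12)
    max_lag = lag.max()
    best = None
    for model in VARIOGRAM_MODELS:
        def resid(p, model=model):
            vg = Variogram(model, p[0], p[1], p[2])
            return w * (vg.gamma(lag) - gam)
        # bounded like automatic variogram fitters: the range cannot exceed
        # the sampled lag span (beyond it the data carry no information) and
        # sills are capped at a multiple of the data variance
        gmax = max(float(gam.max()), var)
        for x0 in ([0.0, var, max_lag / 2.0], [var / 2.0, var / 2.0, max_lag / 4.0]):
            try:
                sol = least_squares(resid, x0=x0,
                                    bounds=([0.0, 0.0, 1e-6 * max_lag],
                                            [5.0 * gmax, 10.0 * gmax, 2.0 * max_lag]))
            except ValueError:
                continue
            sse = float(np.sum(sol.fun ** 2))
            if best is None or sse < best[0]:
                best = (sse, model, sol.x)
    if best is None:  # pragma: no cover
        return Variogram("nugget", var, 0.0, 1.0, emp)
    _, model, p = best
    return Variogram(model, float(p[0]), float(p[1]), float(p[2]), emp)


# ------------------------------------------------------------------ kriging

def deduplicate(coords: np.ndarray, values: np.ndarray):
    """Average values at exactly duplicated coordinates (singularity guard)."""
    df = pd.DataFrame({"lon": coords[:, 0], "lat": coords[:, 1], "v": values})
    agg = df.groupby(["lon", "lat"], as_index=False, sort=False)["v"].mean()
    return agg[["lon", "lat"]].to_numpy(), agg["v"].to_numpy()


class OrdinaryKriging(BaseEstimator):
    """Ordinary kriging with an automatically fitted variogram.

    ``fit(X, y)`` stores deduplicated sample coordinates/values and fits (or
    accepts) a variogram; ``predict(X)`` solves the ordinary-kriging system
    with the unbiasedness (weights-sum-to-one) constraint for every
    prediction point in one factorised solve. The nugget is treated as
    micro-scale variation, so predictions reproduce sample values exactly at
    sample coordinates.

    Parameters
    ----------
    variogram : a fitted :class:`Variogram`, or None to auto-fit.
    n_bins, max_lag_fraction : empirical-variogram controls for auto-fit.
    """

    def __init__(self, variogram: Variogram | None = None, n_bins: int = 12,
                 max_lag_fraction: float = 2.0 / 3.0):
        self.variogram = variogram
        self.n_bins = n_bins
        self.max_lag_fraction = max_lag_fraction

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if len(y) < 2:
            raise InsufficientDataError("kriging needs >= 2 samples")
        X, y = deduplicate(X, y)
        self.X_, self.y_ = X, y
        self.variogram_ = self.variogram or fit_variogram(
            X, y, self.n_bins, self.max_lag_fraction)
        n = len(y)
        vg = self.variogram_
        K = np.empty((n + 1, n + 1))
        K[:n, :n] = vg.covariance(squareform(pdist(X)))
        K[:n, n] = 1.0
        K[n, :n] = 1.0
        K[n, n] = 0.0
        self._K = K
        self._factor = self._factorize(K, n)
        return self

    @staticmethod
    def _factorize(K, n):
        from scipy.linalg import lu_factor
        try:
            lu = lu_factor(K)
            if not np.all(np.isfinite(lu[0])):
                raise np.linalg.LinAlgError
            return lu
        except (np.linalg.LinAlgError, ValueError):
            jit = K.copy()
            jit[:n, :n] += 1e-10 * np.eye(n) * max(abs(K[0, 0]), 1.0)
            try:
                return lu_factor(jit)
            except (np.linalg.LinAlgError, ValueError) as exc:
                raise SingularKrigingError(
                    "singular kriging matrix (duplicate or near-duplicate "
                    "sample locations)") from exc

    def kriging_weights(self, X):
        """(n_samples+1, n_points) solution columns: weights + Lagrange mult."""
        from scipy.linalg import lu_solve
        X = np.atleast_2d(np.asarray(X, float))
        vg = self.variogram_
        d = np.sqrt(((self.X_[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        rhs = np.vstack([vg.covariance(d), np.ones(len(X))])
        return lu_solve(self._factor, rhs)

    def predict(self, X, return_variance: bool = False):
        sol = self.kriging_weights(X)
        w = sol[:-1]
        pred = w.T @ self.y_
        if not return_variance:
            return pred
        vg = self.variogram_
        d = np.sqrt(((self.X_[:, None, :] - np.atleast_2d(X)[None, :, :]) ** 2).sum(-1))
        rhs = np.vstack([vg.covariance(d), np.ones(sol.shape[1])])
        var = vg.total_sill - np.sum(sol * rhs, axis=0)
        return pred, np.maximum(var, 0.0)


# ------------------------------------------------------------------- masks

def build_mask(locations, buffer_deg: float):
    """Convex hull of locations dilated by ``buffer_deg`` (shapely polygon).

    Collinear locations degenerate to a buffered segment, which is allowed
    and logged; a single distinct point is an error.
    """
    pts = np.atleast_2d(np.asarray(locations, float))
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 2:
        raise DegenerateHullError("need >= 2 distinct locations for a mask")
    hull = MultiPoint([tuple(p) for p in uniq]).convex_hull
    if hull.geom_type != "Polygon":
        log.warning("collinear locations: mask degenerates to a buffered segment")
    if buffer_deg > 0:
        hull = hull.buffer(buffer_deg)
    elif hull.geom_type != "Polygon":
        raise DegenerateHullError("collinear locations need a positive buffer")
    return hull


def mask_cells(grid: GridSpec, polygon) -> np.ndarray:
    """Boolean (n_lat, n_lon) array: cell centre inside the polygon."""
    lon2d, lat2d = grid.meshgrid_centers()
    flat = shapely.points(lon2d.ravel(), lat2d.ravel())
    inside = shapely.contains(polygon, flat) | shapely.touches(polygon, flat)
    return inside.reshape(lat2d.shape)


# ---------------------------------------------------------------- surfaces

@dataclass
class IsoscapeSurface:
    """Kriged surface on a grid; NaN outside the mask."""

    grid: GridSpec
    values: np.ndarray          # (n_lat, n_lon); NaN where undefined
    mask: np.ndarray            # boolean, same shape
    provenance: dict = field(default_factory=dict)

    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.values)


def krige(coords, values, grid: GridSpec, vg: Variogram | None = None,
          mask: np.ndarray | None = None, provenance: dict | None = None,
          return_variance: bool = False) -> IsoscapeSurface:
    """Ordinary kriging of point samples onto the masked cells of a grid."""
    ok = OrdinaryKriging(variogram=vg).fit(np.asarray(coords, float),
                                           np.asarray(values, float))
    lon2d, lat2d = grid.meshgrid_centers()
    if mask is None:
        mask = np.ones(lon2d.shape, dtype=bool)
    pts = np.column_stack([lon2d[mask], lat2d[mask]])
    out = np.full(lon2d.shape, np.nan)
    prov = dict(provenance or {}, variogram=ok.variogram_)
    if len(pts):
        if return_variance:
            pred, var = ok.predict(pts, return_variance=True)
            v = np.full(lon2d.shape, np.nan)
            v[mask] = var
            prov["kriging_variance"] = v
        else:
            pred = ok.predict(pts)
        # sanity band: ordinary kriging with smooth (gaussian) models can
        # overshoot far from data; surfaces are clipped to the observed range
        # widened by three sill standard deviations
        s = np.sqrt(max(ok.variogram_.total_sill, 0.0))
        pred = np.clip(pred, ok.y_.min() - 3.0 * s, ok.y_.max() + 3.0 * s)
        out[mask] = pred
    return IsoscapeSurface(grid, out, mask, prov)


def species_isoscape(samples: pd.DataFrame, isotope: str, cell_size: float,
                     buffer_deg: float, vg: Variogram | None = None,
                     provenance: dict | None = None) -> IsoscapeSurface:
    """Hull-masked kriged surface from a locations frame (lon, lat, value)."""
    coords = samples[["lon", "lat"]].to_numpy(float)
    values = samples[isotope].to_numpy(float)
    poly = build_mask(coords, buffer_deg)
    b = poly.bounds
    grid = GridSpec.from_extent(b[0], b[2], b[1], b[3], cell_size)
    mask = mask_cells(grid, poly)
    return krige(coords, values, grid, vg=vg, mask=mask,
                 provenance=dict(provenance or {}, isotope=isotope))


def difference_surface(a: IsoscapeSurface, b: IsoscapeSurface) -> IsoscapeSurface:
    """a - b on the intersection of defined cells (grids must share cell size).

    Grids are aligned by absolute snapped coordinates; no overlap is an
    error (species pairs with disjoint ranges are not comparable).
    """
    if abs(a.grid.cell_size - b.grid.cell_size) > 1e-12:
        raise NoOverlapError("cell sizes differ")
    cs = a.grid.cell_size
    west = max(a.grid.west, b.grid.west)
    south = max(a.grid.south, b.grid.south)
    east = min(a.grid.east, b.grid.east)
    north = min(a.grid.north, b.grid.north)
    if east - west < cs / 2 or north - south < cs / 2:
        raise NoOverlapError("surface extents do not overlap")
    # offsets of the shared window in each grid (snapped grids -> integral)
    def window(g):
        i0 = int(round((west - g.west) / cs))
        j0 = int(round((south - g.south) / cs))
        ni = int(round((east - west) / cs))
        nj = int(round((north - south) / cs))
        return slice(j0, j0 + nj), slice(i0, i0 + ni)
    wa, wb = window(a.grid), window(b.grid)
    va = a.values[wa]
    vb = b.values[wb]
    mask = a.mask[wa] & b.mask[wb] & np.isfinite(va) & np.isfinite(vb)
    if not mask.any():
        raise NoOverlapError("no jointly defined cells")
    out = np.where(mask, va - vb, np.nan)
    grid = GridSpec(cs, west, south, out.shape[1], out.shape[0])
    return IsoscapeSurface(grid, out, mask,
                           {"operation": "difference",
                            "a": a.provenance, "b": b.provenance})


# ---------------------------------------------------------------- bootstrap

def bootstrap_guild_isoscape(per_species: dict[str, pd.DataFrame], isotope: str,
                             k_per_species: int, B: int = 1000, seed: int = 0,
                             cell_size: float = 0.5, buffer_deg: float = 0.5,
                             replace: bool = False):
    """Guild-level mean isoscape over B subsampled replicates.

    Each replicate draws ``k_per_species`` individuals from every species
    (without replacement by default — subsampling equalises per-species n),
    pools them, refits the variogram and kriges onto a fixed guild grid
    (hull + buffer of *all* individuals). Returns ``(mean_surface,
    (lo_envelope, hi_envelope))`` where the envelopes are cell-wise
    min/max across replicates.
    """
    rng = np.random.default_rng(seed)
    for sp, df in per_species.items():
        if not replace and len(df) < k_per_species:
            raise InsufficientIndividualsError(
                f"{sp}: {len(df)} individuals < k={k_per_species}")
    all_df = pd.concat(per_species.values(), ignore_index=True)
    poly = build_mask(all_df[["lon", "lat"]].to_numpy(float), buffer_deg)
    bb = poly.bounds
    grid = GridSpec.from_extent(bb[0], bb[2], bb[1], bb[3], cell_size)
    mask = mask_cells(grid, poly)
    acc = np.zeros(mask.shape)
    lo = np.full(mask.shape, np.inf)
    hi = np.full(mask.shape, -np.inf)
    for b in range(B):
        parts = []
        for sp, df in per_species.items():
            idx = rng.choice(len(df), size=k_per_species, replace=replace)
            parts.append(df.iloc[idx])
        pool = pd.concat(parts, ignore_index=True)
        surf = krige(pool[["lon", "lat"]].to_numpy(float),
                     pool[isotope].to_numpy(float), grid, mask=mask)
        acc += np.where(mask, surf.values, 0.0)
        lo = np.minimum(lo, np.where(mask, surf.values, np.inf))
        hi = np.maximum(hi, np.where(mask, surf.values, -np.inf))
    mean_vals = np.where(mask, acc / B, np.nan)
    prov = {"isotope": isotope, "B": B, "k_per_species": k_per_species,
            "seed": seed, "replace": replace}
    mean_surface = IsoscapeSurface(grid, mean_vals, mask, prov)
    lo = np.where(mask, lo, np.nan)
    hi = np.where(mask, hi, np.nan)
    return mean_surface, (lo, hi)
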