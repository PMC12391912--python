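"""Ordinary kriging with automated variogram fitting.

Vegetation attributes are observed only on a planned subset of sub-blocks
(grass plots in three of the nine sub-blocks, shrub and tree attributes in the
central one).  Unsampled sub-blocks are imputed per variable by ordinary
kriging: an empirical semivariogram is binned from the sampled points, a
spherical/exponential/gaussian model is fitted by pair-count-weighted least
squares, and the best-fitting model supplies the spatial covariances of the
kriging system.  Each variable is kriged independently (no co-kriging) and
bounded variables are clamped to their valid range afterwards, since the
kriging predictor itself is unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

__all__ = [
    "VariogramModel",
    "empirical_variogram",
    "fit_variogram",
    "krige",
    "kriging_weights",
    "impute_grid",
    "InsufficientDataError",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few usable points or bins for a geostatistical fit."""


def _gamma_spherical(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    inside = h < rng
    g = np.where(inside, 1.5 * h / rng - 0.5 * (h / rng) ** 3, 1.0)
    return nugget + psill * np.where(h > 0, g, 0.0)


def _gamma_exponential(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    return nugget + psill * np.where(h > 0, 1.0 - np.exp(-3.0 * h / rng), 0.0)


def _gamma_gaussian(h, nugget, psill, rng):
    h = np.asarray(h, dtype=float)
    return nugget + psill * np.where(h > 0, 1.0 - np.exp(-3.0 * (h / rng) ** 2), 0.0)


_MODELS = {
    "spherical": _gamma_spherical,
    "exponential": _gamma_exponential,
    "gaussian": _gamma_gaussian,
}


@dataclass(frozen=True)
class VariogramModel:
    """Semivariogram: ``gamma(h) = nugget + psill * g(h / range)``, gamma(0)=0."""

    family: str
    nugget: float
    psill: float
    range_: float

    def __post_init__(self):
        if self.family not in _MODELS:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValueError("variogram parameters must satisfy nugget,psill >= 0, range > 0")

    def __call__(self, h):
        return _MODELS[self.family](h, self.nugget, self.psill, self.range_)

    @property
    def sill(self):
        return self.nugget + self.psill


def empirical_variogram(points, values, n_lags=12, max_dist=None):
    """Binned empirical semivariogram ``0.5 * mean[(z_i - z_j)^2]`` per lag.

    Bins with no pairs are dropped.  ``max_dist`` defaults to half the extent
    of the point cloud (a common geostatistical default: long lags carry few,
    highly correlated pairs).
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    points, values = points[ok], values[ok]
    if len(values) < 10:
        raise InsufficientDataError(
            f"empirical variogram needs >= 10 observed points, got {len(values)}"
        )
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(values), k=1)
    d = dist[iu]
    sq = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if max_dist is None:
        max_dist = float(d.max()) / 2.0 if d.max() > 0 else 1.0
    keep = (d > 0) & (d <= max_dist)
    d, sq = d[keep], sq[keep]
    if d.size == 0:
        raise InsufficientDataError("no point pairs within max_dist")
    edges = np.linspace(0.0, max_dist, n_lags + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_lags - 1)
    rows = []
    for b in range(n_lags):
        sel = idx == b
        if not sel.any():
            continue
        rows.append((float(d[sel].mean()), float(sq[sel].mean()), int(sel.sum())))
    lag, semi, npairs = map(np.asarray, zip(*rows))
    return {"lag": lag, "semivariance": semi, "n_pairs": npairs}


def fit_variogram(empirical):
    """Weighted least-squares fit over the three candidate model families.

    Weights are the per-bin pair counts; the family with the smallest weighted
    residual wins.  If no fit converges the fallback is a pure-nugget model at
    the mean semivariance (logged).
    """
    lag = np.asarray(empirical["lag"], dtype=float)
    semi = np.asarray(empirical["semivariance"], dtype=float)
    w = np.asarray(empirical["n_pairs"], dtype=float)
    if lag.size < 3:
        raise InsufficientDataError(f"variogram fit needs >= 3 bins, got {lag.size}")
    if np.allclose(semi, 0.0):
        return VariogramModel("exponential", 0.0, 0.0, float(lag.max()))

    sill0 = max(float(semi[-3:].mean()), 1e-12)
    best = None
    for family, gamma in _MODELS.items():
        p0 = [0.1 * sill0, 0.9 * sill0, float(lag.max()) * 0.5]
        bounds = ([0.0, 0.0, 1e-9], [sill0 * 3, sill0 * 3, float(lag.max()) * 10])
        try:
            popt, _ = optimize.curve_fit(
                gamma, lag, semi, p0=p0, sigma=1.0 / np.sqrt(w), bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = gamma(lag, *popt) - semi
        score = float(np.sum(w * resid**2))
        if best is None or score < best[0]:
            best = (score, family, popt)
    if best is None:
        log.warning("variogram fit failed for all families; falling back to pure nugget")
        return VariogramModel("exponential", float(np.average(semi, weights=w)), 0.0, float(lag.max()))
    _, family, (nugget, psill, rng) = best
    return VariogramModel(family, float(nugget), float(psill), float(rng))


def _dedupe(points, values):
    """Average values at duplicated coordinates (singular-system guard)."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    if len(uniq) == len(points):
        return points, values
    log.info("kriging: %d duplicate points averaged", len(points) - len(uniq))
    sums = np.zeros(len(uniq))
    cnts = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(cnts, inverse, 1.0)
    return uniq, sums / cnts


def kriging_weights(model, obs_points, target):
    """Ordinary-kriging weights and Lagrange multiplier for one target.

    Solves ``[[Gamma, 1], [1', 0]] [w, psi] = [gamma(target), 1]``; the
    weights sum to one (unbiasedness).  Exposed so tests can check against an
    independently solved linear system.
    """
    obs_points = np.asarray(obs_points, dtype=float)
    n = len(obs_points)
    d = np.sqrt(((obs_points[:, None, :] - obs_points[None, :, :]) ** 2).sum(-1))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = model(d)
    np.fill_diagonal(a[:n, :n], 0.0)
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    a[n, n] = 0.0
    dt = np.sqrt(((obs_points - np.asarray(target, dtype=float)) ** 2).sum(-1))
    b = np.empty(n + 1)
    b[:n] = model(dt)
    b[:n][dt == 0] = 0.0
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    return sol[:n], float(sol[n]), b[:n]


def krige(model, obs_points, obs_values, targets, max_neighbors=64, radius_factor=2.0):
    """Ordinary-kriging predictions and variances at the target points.

    The neighborhood is capped at the ``max_neighbors`` nearest observations
    within ``radius_factor`` times the fitted range (falling back to the
    nearest points when none lie inside the radius).
    """
    obs_points, obs_values = _dedupe(obs_points, obs_values)
    if len(obs_values) < 2:
        raise InsufficientDataError("kriging needs >= 2 observed points")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    tree = cKDTree(obs_points)
    radius = radius_factor * model.range_
    k = min(max_neighbors, len(obs_values))
    dist_nn, idx_nn = tree.query(targets, k=k)
    dist_nn = np.atleast_2d(dist_nn)
    idx_nn = np.atleast_2d(idx_nn)

    preds = np.empty(len(targets))
    variances = np.empty(len(targets))
    cache = {}
    for t in range(len(targets)):
        within = dist_nn[t] <= radius
        if not within.any():
            within = np.zeros_like(within, dtype=bool)
            within[: min(8, k)] = True
        nbr = idx_nn[t][within]
        key = tuple(nbr)
        if key in cache:
            a_inv = cache[key]
        else:
            n = len(nbr)
            pts = obs_points[nbr]
            dd = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            a = np.empty((n + 1, n + 1))
            a[:n, :n] = model(dd)
            np.fill_diagonal(a[:n, :n], 0.0)
            a[n, :n] = 1.0
            a[:n, n] = 1.0
            a[n, n] = 0.0
            try:
                a_inv = np.linalg.inv(a)
            except np.linalg.LinAlgError:
                a_inv = np.linalg.pinv(a)
            cache[key] = a_inv
        dt = dist_nn[t][within]
        b = np.empty(len(nbr) + 1)
        b[:-1] = model(dt)
        b[:-1][dt == 0] = 0.0
        b[-1] = 1.0
        sol = a_inv @ b
        w, psi = sol[:-1], sol[-1]
        preds[t] = float(w @ obs_values[nbr])
        variances[t] = max(float(w @ b[:-1] + psi), 0.0)
    return preds, variances


# bounded covariates are clamped after prediction (kriging is unconstrained)
_DEFAULT_BOUNDS = {
    "grass_cover": (0.0, 100.0),
    "shrub_cover": (0.0, 100.0),
    "tree_cover": (0.0, 100.0),
    "grass_color": (1.0, 5.0),
    "shrub_color": (1.0, 5.0),
    "tree_color": (1.0, 5.0),
}


def impute_grid(grid, columns=None, n_lags=12, max_points=2000, max_neighbors=64, seed=0):
    """Impute missing covariate values per variable, year by year.

    Only missing entries are filled; observed values are never touched.  For
    each imputed variable a provenance column ``<name>_provenance`` with
    values ``observed | imputed`` is added.  The variogram is estimated from
    at most ``max_points`` randomly chosen observed sub-blocks to keep the
    pair computation at desk scale.
    """
    cm = grid.colmap
    df = grid.df.copy()
    columns = list(columns or [c for c in cm.covariates if df[c].isna().any()])
    rng = np.random.default_rng(seed)
    for col in columns:
        prov = np.where(df[col].isna(), "imputed", "observed")
        for year in sorted(df[cm.year].unique()):
            sel = df[cm.year] == year
            sub = df[sel]
            obs = sub[col].notna()
            if obs.sum() < 10 or (~obs).sum() == 0:
                if (~obs).sum() > 0:
                    raise InsufficientDataError(
                        f"{col}/{year}: {int(obs.sum())} observed sub-blocks is too few to krige"
                    )
                continue
            pts = sub.loc[obs, [cm.x, cm.y]].to_numpy()
            vals = sub.loc[obs, col].to_numpy()
            if len(vals) > max_points:
                pick = rng.choice(len(vals), size=max_points, replace=False)
                vpts, vvals = pts[pick], vals[pick]
            else:
                vpts, vvals = pts, vals
            emp = empirical_variogram(vpts, vvals, n_lags=n_lags)
            model = fit_variogram(emp)
            targets = sub.loc[~obs, [cm.x, cm.y]].to_numpy()
            if model.sill == 0.0:  # constant field
                preds = np.full(len(targets), float(vals.mean()))
            else:
                preds, _ = krige(model, pts, vals, targets, max_neighbors=max_neighbors)
            if col in _DEFAULT_BOUNDS:
                lo, hi = _DEFAULT_BOUNDS[col]
                preds = np.clip(preds, lo, hi)
            df.loc[sel & df[col].isna(), col] = preds
        df[f"{col}_provenance"] = prov
    out = grid.__class__(df=df, colmap=cm)
    return out
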