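"""Spatial interpolation of well observations onto a regular grid.

The "interpolated" hazard pathway maps each parameter's point
observations onto ~2-km raster grids: ordinary kriging (OK) with an
explicitly fitted semivariogram for every parameter except nitrate,
which uses inverse-distance weighting (IDW) to preserve local variation
and avoid over-smoothing.  Leave-one-out standardized RMSE — the RMS of
(held-out residual / kriging standard deviation) — is the calibration
diagnostic: values near 1 indicate the kriging variances are honest.

Right-skewed (lognormal-like) parameters are kriged in log space and
back-transformed with the +sigma^2/2 lognormal bias correction; pass
``log_transform=False`` to disable.

All solvers are plain numpy/scipy linear algebra: the OK system is the
semivariance matrix augmented with the unbiasedness constraint (weights
sum to 1), solved globally for small networks and over a moving
neighborhood of the nearest ``max_neighbors`` points for large ones.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .grids import GridSpec, InterpMethod, ParameterGrid
from .regions import DistrictMap

__all__ = [
    "VariogramModel",
    "fit_variogram",
    "krige",
    "krige_points",
    "ok_weights",
    "idw",
    "idw_points",
    "loo_standardized_rmse",
    "grid_to_district_values",
    "interpolate_parameter",
]

#: Parameters routed to IDW instead of OK by default.
IDW_PARAMETERS = ("Nitrate",)
DEFAULT_IDW_POWER = 2.0
DEFAULT_IDW_NEIGHBORS = 12
DEFAULT_OK_NEIGHBORS = 32


class VariogramKind(str, enum.Enum):
    SPHERICAL = "spherical"
    EXPONENTIAL = "exponential"
    GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic semivariogram nugget + (sill - nugget) * g(h / range).

    ``range`` is the practical range (exponential and gaussian reach
    ~95% of the sill there).  ``degenerate`` marks constant data, where
    the fit collapses to sill = nugget = 0.
    """

    model: VariogramKind
    nugget: float
    sill: float
    range: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (self.sill >= self.nugget >= 0):
            raise ValueError("need sill >= nugget >= 0")
        if self.range <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        psill = self.sill - self.nugget
        r = self.range
        if self.model == VariogramKind.SPHERICAL:
            hr = np.minimum(h / r, 1.0)
            g = 1.5 * hr - 0.5 * hr**3
        elif self.model == VariogramKind.EXPONENTIAL:
            g = 1.0 - np.exp(-3.0 * h / r)
        else:
            g = 1.0 - np.exp(-3.0 * (h / r) ** 2)
        out = self.nugget + psill * g
        return np.where(h == 0.0, 0.0, out)

    def covariance(self, h: np.ndarray) -> np.ndarray:
        """C(h) = sill - gamma(h) (with C(0) = sill), for simulation."""
        return self.sill - self.__call__(h)


def _observed(points: pd.DataFrame, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    sub = points.loc[points[parameter].notna(), ["x", "y", parameter]]
    coords = sub[["x", "y"]].to_numpy(dtype=float)
    return coords, sub[parameter].to_numpy(dtype=float)


def _dedup(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at duplicate coordinates (kriging needs distinct points)."""
    uniq, inv = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    warnings.warn("duplicate well coordinates: averaging values per location")
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inv, values)
    np.add.at(counts, inv, 1)
    return uniq, sums / counts


def _fit_one_model(
    kind: VariogramKind,
    h_emp: np.ndarray,
    g_emp: np.ndarray,
    counts: np.ndarray,
    var: float,
    max_lag: float,
) -> tuple[VariogramModel, float]:
    """Cressie-weighted least squares for one model family.

    Residuals are weighted by sqrt(N_j) / gamma_model(h_j): pair-rich
    bins count more, and the short lags — which control interpolation
    behaviour and the nugget — are strongly upweighted relative to the
    large far-lag semivariances.  Returns the model and its weighted SSE
    (for model selection).
    """

    def resid(theta: np.ndarray) -> np.ndarray:
        nugget, psill, rng_ = theta
        vm = VariogramModel(kind, nugget, nugget + psill, rng_)
        gm = np.maximum(vm(h_emp), 1e-12 * var)
        return np.sqrt(counts) / gm * (vm(h_emp) - g_emp)

    fit = least_squares(
        resid,
        x0=np.array([1e-3 * var, var, max_lag / 2.0]),
        bounds=([0.0, 1e-12 * var, 1e-6 * max_lag], [var * 10, var * 10, max_lag * 10]),
    )
    nugget, psill, rng_ = fit.x
    return (
        VariogramModel(kind, float(nugget), float(nugget + psill), float(rng_)),
        float((fit.fun**2).sum()),
    )


def fit_variogram(
    points: pd.DataFrame,
    parameter: str,
    model: VariogramKind | str | None = VariogramKind.SPHERICAL,
    n_lags: int = 15,
    max_lag: float | None = None,
) -> VariogramModel:
    """Fit an isotropic variogram model by weighted least squares.

    The empirical semivariogram is the mean of half squared differences
    within ``n_lags`` equal-width distance bins (up to ``max_lag``,
    default half the maximum pairwise distance), fitted with Cressie
    weights (pair count / model semivariance squared) so short lags are
    not drowned out by the far-lag bins.  ``model=None`` (or ``"auto"``)
    fits all three families and keeps the lowest weighted SSE.
    Requires >= 10 observed points.
    """
    kinds = (
        list(VariogramKind)
        if model is None or model == "auto"
        else [VariogramKind(model)]
    )
    coords, values = _observed(points, parameter)
    coords, values = _dedup(coords, values)
    if len(values) < 10:
        raise ValueError(f"variogram fit needs >= 10 points, got {len(values)}")
    if np.ptp(values) == 0.0:
        return VariogramModel(kinds[0], 0.0, 0.0, 1.0, degenerate=True)

    d = pdist(coords)
    g = 0.5 * pdist(values[:, None]) ** 2
    if max_lag is None:
        max_lag = d.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_lags + 1)
    which = np.digitize(d, edges) - 1
    keep = (which >= 0) & (which < n_lags)
    counts = np.bincount(which[keep], minlength=n_lags).astype(float)
    sums = np.bincount(which[keep], weights=g[keep], minlength=n_lags)
    nonempty = counts > 0
    h_emp = 0.5 * (edges[:-1] + edges[1:])[nonempty]
    g_emp = sums[nonempty] / counts[nonempty]
    var = values.var()

    fits = [_fit_one_model(k, h_emp, g_emp, counts[nonempty], var, max_lag) for k in kinds]
    return min(fits, key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# ordinary kriging


def ok_weights(
    coords: np.ndarray, variogram: VariogramModel, query: np.ndarray
) -> tuple[np.ndarray, float]:
    """Solve the OK system for one query point.

    Returns the n kriging weights (they sum to 1 by the unbiasedness
    constraint) and the Lagrange multiplier.  Mostly useful for tests
    and diagnostics; :func:`krige_points` is the vectorized path.
    """
    n = len(coords)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = variogram(squareform(pdist(coords)))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    b = np.empty(n + 1)
    b[:n] = variogram(np.linalg.norm(coords - query, axis=1))
    b[n] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:n], float(sol[n])


def _ok_solve_global(
    coords: np.ndarray,
    values: np.ndarray,
    variogram: VariogramModel,
    qx: np.ndarray,
    qy: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(coords)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = variogram(squareform(pdist(coords)))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    q = np.column_stack([qx, qy])
    d = np.sqrt(((q[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    B = np.empty((n + 1, len(q)))
    B[:n] = variogram(d).T
    B[n] = 1.0
    if variogram.model == VariogramKind.GAUSSIAN and variogram.nugget < 1e-12:
        A[:n, :n] += np.eye(n) * variogram.sill * 1e-8  # gaussian models are near-singular without a nugget
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        warnings.warn("ill-conditioned kriging system: adding ridge jitter")
        A[:n, :n] += np.eye(n) * max(variogram.sill, 1.0) * 1e-8
        sol = np.linalg.solve(A, B)
    w, mu = sol[:n], sol[n]
    pred = w.T @ values
    var = np.einsum("nq,nq->q", w, B[:n]) + mu
    return pred, np.maximum(var, 0.0)


def _ok_solve_moving(
    coords: np.ndarray,
    values: np.ndarray,
    variogram: VariogramModel,
    qx: np.ndarray,
    qy: np.ndarray,
    k: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched per-query OK over the k nearest neighbors."""
    tree = cKDTree(coords)
    q = np.column_stack([qx, qy])
    dist, idx = tree.query(q, k=k)
    m = len(q)
    nb = coords[idx]  # (m, k, 2)
    dd = np.sqrt(((nb[:, :, None, :] - nb[:, None, :, :]) ** 2).sum(-1))
    A = np.zeros((m, k + 1, k + 1))
    A[:, :k, :k] = variogram(dd)
    A[:, :k, k] = 1.0
    A[:, k, :k] = 1.0
    b = np.empty((m, k + 1))
    b[:, :k] = variogram(dist)
    b[:, k] = 1.0
    if variogram.model == VariogramKind.GAUSSIAN and variogram.nugget < 1e-12:
        A[:, :k, :k] += np.eye(k) * variogram.sill * 1e-8
    try:
        sol = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        warnings.warn("ill-conditioned kriging neighborhoods: adding ridge jitter")
        A[:, :k, :k] += np.eye(k) * max(variogram.sill, 1.0) * 1e-8
        sol = np.linalg.solve(A, b[..., None])[..., 0]
    w, mu = sol[:, :k], sol[:, k]
    pred = (w * values[idx]).sum(axis=1)
    var = (w * b[:, :k]).sum(axis=1) + mu
    return pred, np.maximum(var, 0.0)


def krige_points(
    points: pd.DataFrame,
    parameter: str,
    variogram: VariogramModel,
    qx: np.ndarray,
    qy: np.ndarray,
    max_neighbors: int | None = DEFAULT_OK_NEIGHBORS,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging prediction and variance at arbitrary points."""
    coords, values = _observed(points, parameter)
    coords, values = _dedup(coords, values)
    if len(values) < 3:
        raise ValueError(f"kriging needs >= 3 distinct points, got {len(values)}")
    qx = np.asarray(qx, dtype=float)
    qy = np.asarray(qy, dtype=float)
    if max_neighbors is None or len(values) <= max_neighbors:
        return _ok_solve_global(coords, values, variogram, qx, qy)
    return _ok_solve_moving(coords, values, variogram, qx, qy, max_neighbors)


def krige(
    points: pd.DataFrame,
    parameter: str,
    variogram: VariogramModel,
    spec: GridSpec,
    max_neighbors: int | None = DEFAULT_OK_NEIGHBORS,
) -> ParameterGrid:
    """Ordinary kriging of one parameter onto every grid-cell centre.

    With a zero-nugget variogram the predictor is exact at data
    locations.  Duplicate coordinates are averaged with a warning.
    """
    gx, gy = spec.center_points()
    pred, var = krige_points(points, parameter, variogram, gx, gy, max_neighbors)
    return ParameterGrid(
        parameter=parameter,
        spec=spec,
        values=pred.reshape(spec.shape),
        variance=var.reshape(spec.shape),
        method=InterpMethod.ORDINARY_KRIGING,
    )


# ---------------------------------------------------------------------------
# inverse-distance weighting


def idw_points(
    points: pd.DataFrame,
    parameter: str,
    qx: np.ndarray,
    qy: np.ndarray,
    power: float = DEFAULT_IDW_POWER,
    max_neighbors: int = DEFAULT_IDW_NEIGHBORS,
) -> np.ndarray:
    """IDW prediction at arbitrary points (exact at data locations)."""
    if power <= 0:
        raise ValueError("power must be positive")
    coords, values = _observed(points, parameter)
    coords, values = _dedup(coords, values)
    if len(values) < 1:
        raise ValueError("IDW needs at least 1 observed point")
    k = min(max_neighbors, len(values))
    tree = cKDTree(coords)
    q = np.column_stack([np.asarray(qx, dtype=float), np.asarray(qy, dtype=float)])
    dist, idx = tree.query(q, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    hit = dist[:, 0] == 0.0  # coincident with a data point: return it exactly
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[hit] = 0.0
    w[hit, 0] = 1.0
    pred = (w * values[idx]).sum(axis=1) / w.sum(axis=1)
    return pred


def idw(
    points: pd.DataFrame,
    parameter: str,
    spec: GridSpec,
    power: float = DEFAULT_IDW_POWER,
    max_neighbors: int = DEFAULT_IDW_NEIGHBORS,
) -> ParameterGrid:
    """Inverse-distance-weighted interpolation onto the grid; predictions
    are convex combinations of the nearest neighbours' values."""
    gx, gy = spec.center_points()
    pred = idw_points(points, parameter, gx, gy, power, max_neighbors)
    return ParameterGrid(
        parameter=parameter, spec=spec, values=pred.reshape(spec.shape),
        method=InterpMethod.IDW,
    )


# ---------------------------------------------------------------------------
# diagnostics


def loo_standardized_rmse(
    points: pd.DataFrame,
    parameter: str,
    variogram: VariogramModel | None = None,
    model: VariogramKind | str = VariogramKind.SPHERICAL,
    max_neighbors: int = DEFAULT_OK_NEIGHBORS,
) -> float:
    """Leave-one-out root-mean-square standardized error of OK.

    Each observation is predicted from the remaining points and its
    residual divided by the predicted kriging standard deviation; the
    RMS of those ratios is ~1 when the variogram calibrates the
    prediction uncertainty well.  Points with zero predicted variance
    are skipped with a warning.
    """
    coords, values = _observed(points, parameter)
    coords, values = _dedup(coords, values)
    n = len(values)
    if n < 10:
        raise ValueError(f"LOO diagnostic needs >= 10 points, got {n}")
    if variogram is None:
        variogram = fit_variogram(points, parameter, model)
    k = min(max_neighbors, n - 1)
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    nb = coords[idx]
    dd = np.sqrt(((nb[:, :, None, :] - nb[:, None, :, :]) ** 2).sum(-1))
    A = np.zeros((n, k + 1, k + 1))
    A[:, :k, :k] = variogram(dd)
    A[:, :k, k] = 1.0
    A[:, k, :k] = 1.0
    b = np.empty((n, k + 1))
    b[:, :k] = variogram(dist)
    b[:, k] = 1.0
    sol = np.linalg.solve(A, b[..., None])[..., 0]
    w, mu = sol[:, :k], sol[:, k]
    pred = (w * values[idx]).sum(axis=1)
    var = (w * b[:, :k]).sum(axis=1) + mu
    ok = var > 0
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} points with zero predicted kriging variance")
    z = (values[ok] - pred[ok]) / np.sqrt(var[ok])
    return float(np.sqrt(np.mean(z**2)))


def grid_to_district_values(
    grid: ParameterGrid, districts: DistrictMap
) -> dict[str, np.ndarray]:
    """Pool grid values by the district containing each cell centre.

    Cells outside every district are dropped; districts containing no
    cell centre are excluded with a warning (they cannot contribute to
    a grid-based index).  Boundary cells go to the lowest district id.
    """
    gx, gy = grid.spec.center_points()
    ids = districts.assign_points(gx, gy)
    flat = grid.values.ravel()
    out: dict[str, np.ndarray] = {}
    for did in districts.ids:
        sel = ids == did
        if not sel.any():
            warnings.warn(f"district {did} contains no grid-cell centres; excluded")
            continue
        out[did] = flat[sel]
    return out


def interpolate_parameter(
    points: pd.DataFrame,
    parameter: str,
    spec: GridSpec,
    method: InterpMethod | str | None = None,
    variogram_model: VariogramKind | str | None = None,
    log_transform: bool = True,
    idw_power: float = DEFAULT_IDW_POWER,
    idw_neighbors: int = DEFAULT_IDW_NEIGHBORS,
    ok_neighbors: int | None = DEFAULT_OK_NEIGHBORS,
) -> ParameterGrid:
    """Route one parameter through its default interpolator.

    Nitrate goes to IDW (power 2, 12 neighbours) to preserve local
    variation; everything else is ordinary-kriged, by default in log
    space with the lognormal +sigma^2/2 back-transform (concentrations
    are strictly positive and right-skewed).
    """
    if method is None:
        method = InterpMethod.IDW if parameter in IDW_PARAMETERS else InterpMethod.ORDINARY_KRIGING
    method = InterpMethod(method)
    if method == InterpMethod.IDW:
        return idw(points, parameter, spec, idw_power, idw_neighbors)
    if log_transform:
        work = points[["x", "y", parameter]].copy()
        vals = work[parameter]
        if (vals.dropna() <= 0).any():
            raise ValueError(f"log-space kriging needs positive {parameter} values")
        work[parameter] = np.log(vals)
    else:
        work = points
    vm = fit_variogram(work, parameter, variogram_model)
    if vm.degenerate:
        const = work[parameter].dropna().iloc[0]
        values = np.full(spec.shape, np.exp(const) if log_transform else const)
        return ParameterGrid(parameter=parameter, spec=spec, values=values,
                             method=InterpMethod.ORDINARY_KRIGING)
    out = krige(work, parameter, vm, spec, ok_neighbors)
    if log_transform:
        out.values = np.exp(out.values + 0.5 * out.variance)
        out.variance = None  # log-space variance no longer applies
    out.parameter = parameter
    return out
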