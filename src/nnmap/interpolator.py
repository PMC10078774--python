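"""Nearest-neighbor spatial interpolation with exact tie averaging.

The interpolated value at a query location is the observed value at its
nearest sampled location; when several sampled locations are (numerically)
equidistant — the tie set ``H_p`` — their observations are averaged. A query
coinciding with a sampled location returns that observation exactly. The
resulting map is piecewise constant: Voronoi cells of the sample in the
continuous setting, quadrats in the area setting, and unit points in the
unit setting.

An inverse-distance-weighting (IDW) interpolator is included: the NN rule is
its limit as the distance-decay exponent grows, which the test-suite uses as
an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .populations import AreaPopulation, UnitPopulation
from .sampling import SampleRealization

__all__ = [
    "EstimatedMap",
    "nn_values",
    "nn_interpolate",
    "nn_map_areas",
    "nn_map_units",
    "residual_interpolate",
    "idw_interpolate",
    "DEFAULT_TIE_TOL",
]

#: Absolute distance tolerance (region units) for coincidence and tie sets.
#: Exact ties arise only on lattices where symmetric distances are equal in
#: floating point; the tolerance guards quantisation noise.
DEFAULT_TIE_TOL = 1e-9

# Below this many sample points a vectorised full distance scan beats a tree.
_BRUTE_FORCE_MAX_N = 64


@dataclass(frozen=True)
class EstimatedMap:
    """A piecewise-constant interpolated field over a finite support."""

    setting: str  # 'continuous' | 'areas' | 'units'
    support: np.ndarray  # (nq, 2) evaluation locations
    values: np.ndarray  # (nq,) interpolated values
    sample: SampleRealization | None = None  # provenance
    grid_shape: tuple[int, int] | None = None  # (ny, nx) when support is a grid

    @property
    def n_support(self) -> int:
        return len(self.support)


def nn_values(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    query_xy: np.ndarray,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> np.ndarray:
    """Core NN rule: tie-averaged nearest observed value per query point.

    All sampled locations whose distance to the query is within ``tie_tol``
    of the minimum distance form the tie set; their values are averaged.
    """
    sxy = np.asarray(sample_xy, dtype=float)
    svals = np.asarray(sample_values, dtype=float)
    qxy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    if len(sxy) == 0:
        raise ValueError("cannot interpolate from an empty sample")
    if len(sxy) == 1:
        return np.full(len(qxy), svals[0])

    if len(sxy) <= _BRUTE_FORCE_MAX_N:
        d = np.sqrt(
            ((qxy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2)
        )  # (nq, n)
        dmin = d.min(axis=1)
        tie = d <= (dmin[:, None] + tie_tol)
        return (tie * svals[None, :]).sum(axis=1) / tie.sum(axis=1)

    tree = cKDTree(sxy)
    dmin, nearest = tree.query(qxy)
    out = svals[nearest]
    # resolve ties only where a second sampled point is within tolerance
    d2, _ = tree.query(qxy, k=2)
    maybe_tied = np.flatnonzero(d2[:, 1] <= d2[:, 0] + tie_tol)
    for i in maybe_tied:
        idx = tree.query_ball_point(qxy[i], dmin[i] + tie_tol)
        out[i] = svals[idx].mean()
    return out


def nn_interpolate(
    sample: SampleRealization,
    query_points: np.ndarray,
    values: np.ndarray | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
    grid_shape: tuple[int, int] | None = None,
) -> EstimatedMap:
    """NN-interpolate a continuous-setting sample onto query points.

    ``values`` overrides the observations carried by the realization (used by
    the bootstrap, which reads values off a pseudopopulation field).
    """
    vals = sample.values if values is None else np.asarray(values, dtype=float)
    if vals is None:
        raise ValueError("sample carries no observed values")
    est = nn_values(sample.locations, vals, query_points, tie_tol)
    return EstimatedMap(
        "continuous", np.atleast_2d(np.asarray(query_points, dtype=float)), est,
        sample=sample, grid_shape=grid_shape,
    )


def nn_map_areas(
    sample: SampleRealization,
    area_pop: AreaPopulation,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> EstimatedMap:
    """NN map over all area centroids from a sample of areas.

    Sampled areas keep their own observed density exactly (distance zero to
    their own centroid); unsampled areas receive the tie-averaged density of
    the nearest sampled centroid(s) — on a regular quadrat grid several
    centroids can be exactly equidistant.
    """
    if sample.indices is None:
        raise ValueError("area samples must carry selected indices")
    if np.any(sample.indices >= area_pop.N):
        raise ValueError("sample indices outside the population")
    centroids = area_pop.centroids
    est = nn_values(centroids[sample.indices], sample.values, centroids, tie_tol)
    return EstimatedMap("areas", centroids, est, sample=sample,
                        grid_shape=(area_pop.g, area_pop.g))


def nn_map_units(
    sample: SampleRealization,
    unit_pop: UnitPopulation,
    values: np.ndarray | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> EstimatedMap:
    """NN map over all unit locations from a sample of units."""
    vals = sample.values if values is None else np.asarray(values, dtype=float)
    est = nn_values(sample.locations, vals, unit_pop.locations, tie_tol)
    return EstimatedMap("units", unit_pop.locations, est, sample=sample)


def residual_interpolate(
    sample: SampleRealization,
    unit_pop: UnitPopulation,
    residuals: np.ndarray | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> EstimatedMap:
    """Prediction-assisted NN map: interpolate residuals, add predictions back.

    Under 3P sampling the prediction errors ``e_i = y_i - x_i`` are observed
    for sampled units; interpolating them and reconstructing
    ``y^_j = x_j + e^_j`` typically maps far better than interpolating the
    raw values, because jumps in ``y`` are largely absorbed by ``x``. Sampled
    units recover their own value exactly.
    """
    if unit_pop.predictions is None:
        raise ValueError("residual interpolation requires frame-wide predictions")
    e = sample.residuals if residuals is None else np.asarray(residuals, dtype=float)
    e_hat = nn_values(sample.locations, e, unit_pop.locations, tie_tol)
    y_hat = unit_pop.predictions + e_hat
    return EstimatedMap("units", unit_pop.locations, y_hat, sample=sample)


def idw_interpolate(
    sample_xy: np.ndarray,
    sample_values: np.ndarray,
    query_xy: np.ndarray,
    alpha: float,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> np.ndarray:
    """Inverse-distance-weighted interpolation with weights ``d**-alpha``.

    A query within ``tie_tol`` of a sampled location returns that observation
    (the coincidence branch of the estimator). As ``alpha`` grows the weights
    concentrate on the nearest sampled point and the IDW map converges to the
    NN map away from ties.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    sxy = np.asarray(sample_xy, dtype=float)
    svals = np.asarray(sample_values, dtype=float)
    qxy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    d = np.sqrt(((qxy[:, None, :] - sxy[None, :, :]) ** 2).sum(axis=2))
    out = np.empty(len(qxy))
    coincident = d.min(axis=1) <= tie_tol
    for i in np.flatnonzero(coincident):
        out[i] = svals[np.argmin(d[i])]
    free = ~coincident
    if free.any():
        # normalise by the minimum distance before exponentiating to avoid
        # overflow/underflow at large alpha
        df = d[free]
        rel = df / df.min(axis=1, keepdims=True)
        w = rel**-alpha
        out[free] = (w * svals[None, :]).sum(axis=1) / w.sum(axis=1)
    return out
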