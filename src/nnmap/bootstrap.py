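"""Pseudopopulation bootstrap estimation of NN-map root mean squared errors.

The estimated map is treated as a complete surrogate population; bootstrap
samples are drawn from it with the *same* design used for the original
sample, each is NN-interpolated reading values off the surrogate, and the
per-location RMSE estimate is

    rmse*(p) = sqrt( (1/M) * sum_m (f^*_m(p) - f^(p))**2 ).

In the continuous setting the surrogate field is the Voronoi field of the
original sample (exact nearest-original-point lookup), not a discretised
display grid, so no second layer of discretisation error enters the
bootstrap values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .interpolator import (
    DEFAULT_TIE_TOL,
    EstimatedMap,
    nn_values,
)
from .populations import (
    AreaPopulation,
    ContinuousPopulation,
    StudyRegion,
    UNIT_SQUARE,
    UnitPopulation,
)
from .sampling import (
    CONTINUOUS_SCHEMES,
    FINITE_SCHEMES,
    SchemeSpec,
    draw,
    draw_locations_many,
    draw_threep,
)

__all__ = ["BootstrapReport", "build_pseudopopulation", "bootstrap_rmse",
           "threep_bootstrap_rmse"]

# Batch the fully-vectorised continuous path only while the (M, n, q) distance
# tensor stays comfortably in memory.
_BATCH_ELEMENT_CAP = 20_000_000


@dataclass(frozen=True)
class BootstrapReport:
    """Per-support-point bootstrap RMSE of the NN interpolator."""

    support: np.ndarray  # (nq, 2)
    rmse_star: np.ndarray  # (nq,)
    boot_mean: np.ndarray  # mean of bootstrap values per point
    M: int
    spec: SchemeSpec


def build_pseudopopulation(
    est_map: EstimatedMap, region: StudyRegion = UNIT_SQUARE
):
    """Promote an estimated map to a complete surrogate population.

    continuous
        The Voronoi field of the original sample: the value anywhere is the
        value observed at the nearest original sampled location. Requires the
        map to carry its generating sample.
    areas
        An :class:`AreaPopulation` whose densities are the mapped densities;
        the map must cover every quadrat of its grid.
    units
        A :class:`UnitPopulation` carrying the mapped values at every unit.
    """
    if est_map.setting == "continuous":
        sample = est_map.sample
        if sample is None or sample.values is None:
            raise ValueError(
                "continuous pseudopopulation needs the generating sample"
            )
        sxy, svals = sample.locations, sample.values

        def density(points: np.ndarray) -> np.ndarray:
            return nn_values(sxy, svals, points)

        return ContinuousPopulation(region, density, L=float(np.max(svals)))
    if est_map.setting == "areas":
        if est_map.grid_shape is None:
            raise ValueError("area map lost its grid shape")
        g = est_map.grid_shape[0]
        if est_map.n_support != g * g:
            raise ValueError("area map must cover every quadrat")
        cell_area = region.area / (g * g)
        return AreaPopulation(region, g, est_map.values * cell_area)
    if est_map.setting == "units":
        return UnitPopulation(est_map.support, est_map.values, region=region)
    raise ValueError(f"unknown setting {est_map.setting!r}")


def _continuous_bootstrap_values(
    sample_xy: np.ndarray,
    pseudo_vals_fn,
    spec: SchemeSpec,
    support: np.ndarray,
    M: int,
    rng: np.random.Generator,
    region: StudyRegion,
    tie_tol: float,
) -> np.ndarray:
    """Bootstrap NN values at the support, shape (M, nq)."""
    locs = draw_locations_many(spec, region, M, rng)  # (M, n, 2)
    n = locs.shape[1]
    flat = locs.reshape(-1, 2)
    pvals = np.asarray(pseudo_vals_fn(flat)).reshape(M, n)
    nq = len(support)
    if M * n * nq <= _BATCH_ELEMENT_CAP:
        # squared distances via the quadratic expansion: avoids a 4-D temporary
        d2 = (
            (locs**2).sum(axis=2)[:, :, None]
            + (support**2).sum(axis=1)[None, None, :]
            - 2.0 * locs @ support.T
        )
        np.maximum(d2, 0.0, out=d2)
        d2min = d2.min(axis=1)  # (M, nq)
        dmin = np.sqrt(d2min)
        tie = d2 <= (dmin[:, None, :] + tie_tol) ** 2
        return (tie * pvals[:, :, None]).sum(axis=1) / tie.sum(axis=1)
    out = np.empty((M, nq))
    for m in range(M):
        out[m] = nn_values(locs[m], pvals[m], support, tie_tol)
    return out


def bootstrap_rmse(
    est_map: EstimatedMap,
    spec: SchemeSpec,
    M: int,
    rng: np.random.Generator,
    region: StudyRegion = UNIT_SQUARE,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> BootstrapReport:
    """Pseudopopulation bootstrap RMSE of the NN map at its support points.

    ``spec`` must be the design that produced the original sample (same
    scheme type and parameters); mismatched settings raise before any
    resampling.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    setting = est_map.setting
    if setting == "continuous" and spec.scheme not in CONTINUOUS_SCHEMES:
        raise ValueError(f"scheme {spec.scheme!r} cannot resample a continuous map")
    if setting == "areas" and spec.scheme not in FINITE_SCHEMES:
        raise ValueError(f"scheme {spec.scheme!r} cannot resample an area map")
    if setting == "units" and spec.scheme not in FINITE_SCHEMES + ("threep",):
        raise ValueError(f"scheme {spec.scheme!r} cannot resample a unit map")

    pseudo = build_pseudopopulation(est_map, region)
    fhat = est_map.values
    support = est_map.support

    if setting == "continuous":
        boot = _continuous_bootstrap_values(
            est_map.sample.locations, pseudo.density, spec, support, M, rng,
            region, tie_tol,
        )
    else:
        boot = np.empty((M, len(support)))
        for m in range(M):
            sample = draw(spec, pseudo, rng)
            boot[m] = nn_values(sample.locations, sample.values, support, tie_tol)

    rmse_star = np.sqrt(((boot - fhat[None, :]) ** 2).mean(axis=0))
    return BootstrapReport(support, rmse_star, boot.mean(axis=0), M, spec)


def threep_bootstrap_rmse(
    est_map: EstimatedMap,
    unit_pop: UnitPopulation,
    M: int,
    rng: np.random.Generator,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> BootstrapReport:
    """Bootstrap RMSE for the prediction-assisted (3P residual) workflow.

    The surrogate population carries the mapped values ``y^_j``; every
    bootstrap replicate draws a 3P sample with the original frame
    probabilities ``pi_j``, interpolates the pseudo-residuals
    ``y^_j - x_j``, and rebuilds the bootstrap map as ``x_j + e^*_j``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if est_map.setting != "units":
        raise ValueError("3P bootstrap applies to unit-population maps")
    if unit_pop.predictions is None or unit_pop.pi is None:
        raise ValueError("3P bootstrap requires frame predictions and probabilities")
    if est_map.n_support != unit_pop.N:
        raise ValueError("map support and population size disagree")

    y_hat = est_map.values
    pseudo_resid = y_hat - unit_pop.predictions
    pseudo_pop = replace(unit_pop, values=y_hat)
    boot = np.empty((M, unit_pop.N))
    for m in range(M):
        sample = draw_threep(pseudo_pop, rng)
        idx = sample.indices
        e_star = nn_values(
            unit_pop.locations[idx], pseudo_resid[idx], unit_pop.locations, tie_tol
        )
        boot[m] = unit_pop.predictions + e_star
    rmse_star = np.sqrt(((boot - y_hat[None, :]) ** 2).mean(axis=0))
    return BootstrapReport(
        unit_pop.locations, rmse_star, boot.mean(axis=0), M, SchemeSpec("threep")
    )
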