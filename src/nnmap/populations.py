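"""Spatial populations for design-based mapping.

Three settings are supported, mirroring how survey variables arise in
environmental and forest surveys:

* **continuous** populations — a bounded density ``f`` on a rectangular study
  region, observable at any location;
* **area** populations — the region partitioned into a regular grid of
  quadrats, each carrying a total amount of the survey variable (hence a
  per-area density);
* **unit** populations — a finite set of point-located units with bounded
  values, optionally carrying expert predictions and inclusion probabilities
  for probability-proportional-to-prediction (3P) sampling.

The module also provides the three canonical benchmark surfaces on the unit
square used throughout the simulation machinery, with normalising constants
derived numerically so that every surface attains a maximum of ``L = 10``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "StudyRegion",
    "UNIT_SQUARE",
    "ContinuousPopulation",
    "AreaPopulation",
    "UnitPopulation",
    "eval_surface",
    "surface_function",
    "derive_constants",
    "continuous_population",
    "make_area_population",
    "generate_unit_pattern",
    "assign_surface_values",
    "truncate_units",
    "make_predictions",
    "threep_pi_floor",
    "DEFAULT_L",
]

#: Common upper bound for all benchmark surveys variables.
DEFAULT_L = 10.0

UNIT_PATTERNS = ("regular", "random", "trended", "clustered")


@dataclass(frozen=True)
class StudyRegion:
    """Axis-aligned rectangular study region with its Lebesgue measure."""

    xmin: float = 0.0
    ymin: float = 0.0
    xmax: float = 1.0
    ymax: float = 1.0

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("study region must have positive width and height")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def diameter(self) -> float:
        return math.hypot(self.width, self.height)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.xmin, self.ymin, self.xmax, self.ymax)

    def contains(self, points: np.ndarray, atol: float = 0.0) -> np.ndarray:
        """Boolean mask of points lying inside the (closed) rectangle."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return (
            (p[:, 0] >= self.xmin - atol)
            & (p[:, 0] <= self.xmax + atol)
            & (p[:, 1] >= self.ymin - atol)
            & (p[:, 1] <= self.ymax + atol)
        )


UNIT_SQUARE = StudyRegion()


@dataclass(frozen=True)
class ContinuousPopulation:
    """A fixed scalar field ``f`` on a study region, bounded in ``[0, L]``."""

    region: StudyRegion
    density: Callable[[np.ndarray], np.ndarray]
    L: float = DEFAULT_L

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.density(points)


@dataclass(frozen=True)
class AreaPopulation:
    """A ``g x g`` quadrat partition of the region with per-area totals.

    Quadrats are indexed row-major from the lower-left corner:
    quadrat ``j = row * g + col`` covers
    ``[xmin + col*w, xmin + (col+1)*w) x [ymin + row*h, ymin + (row+1)*h)``.
    """

    region: StudyRegion
    g: int
    totals: np.ndarray  # amount of Y per quadrat, shape (g*g,)
    L: float = DEFAULT_L

    @property
    def N(self) -> int:
        return self.g * self.g

    @property
    def cell_area(self) -> float:
        return self.region.area / self.N

    @property
    def densities(self) -> np.ndarray:
        return self.totals / self.cell_area

    @property
    def centroids(self) -> np.ndarray:
        g, r = self.g, self.region
        w, h = r.width / g, r.height / g
        cols = np.arange(g)
        rows = np.arange(g)
        cx = r.xmin + (cols + 0.5) * w
        cy = r.ymin + (rows + 0.5) * h
        gx, gy = np.meshgrid(cx, cy)  # gy varies along rows
        return np.column_stack([gx.ravel(), gy.ravel()])

    def quadrat_index(self, points: np.ndarray) -> np.ndarray:
        """Row-major quadrat index of each point (boundary points clipped in)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        r = self.region
        col = np.clip(
            np.floor((p[:, 0] - r.xmin) / r.width * self.g).astype(int), 0, self.g - 1
        )
        row = np.clip(
            np.floor((p[:, 1] - r.ymin) / r.height * self.g).astype(int), 0, self.g - 1
        )
        return row * self.g + col

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """The piecewise-constant density field evaluated at arbitrary points."""
        return self.densities[self.quadrat_index(points)]


@dataclass(frozen=True)
class UnitPopulation:
    """Point-located units with values and optional 3P frame data.

    Nested populations (increasing size ladders) share their common prefix of
    locations exactly; ``level`` records the position in the ladder.
    """

    locations: np.ndarray  # (N, 2)
    values: np.ndarray | None = None  # (N,)
    predictions: np.ndarray | None = None
    pi: np.ndarray | None = None
    region: StudyRegion = UNIT_SQUARE
    pattern: str | None = None
    level: int | None = None
    L: float = DEFAULT_L

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        object.__setattr__(self, "locations", loc)
        if loc.ndim != 2 or loc.shape[1] != 2:
            raise ValueError("locations must have shape (N, 2)")
        if not self.region.contains(loc, atol=1e-12).all():
            raise ValueError("all unit locations must lie inside the region")
        for name in ("values", "predictions", "pi"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(loc),):
                    raise ValueError(f"{name} must have shape (N,)")
                object.__setattr__(self, name, arr)
        if self.pi is not None and ((self.pi <= 0) | (self.pi > 1)).any():
            raise ValueError("inclusion probabilities must lie in (0, 1]")

    @property
    def N(self) -> int:
        return len(self.locations)


# ---------------------------------------------------------------------------
# Benchmark surfaces on the unit square
# ---------------------------------------------------------------------------

def _surface_raw(surface_id: int, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Unnormalised benchmark surfaces (before scaling to max value L).

    Surface 1 is smooth (Lipschitz) with a mild trend, surface 2 is a smooth
    oscillating bump, and surface 3 is discontinuous exactly on the internal
    edges of the upper-right quadrant of the unit square.
    """
    if surface_id == 1:
        return 0.5 * (np.sin(p1) ** 2 + np.cos(p2) ** 2 + p1)
    if surface_id == 2:
        return np.sin(3.0 * p1) * np.sin(3.0 * p2) ** 2
    if surface_id == 3:
        low = np.minimum(p1, p2) <= 0.5
        return np.where(low, p1 * p2, (1.0 + p1) * p2)
    raise ValueError(f"unknown surface id {surface_id!r} (expected 1, 2 or 3)")


@lru_cache(maxsize=None)
def derive_constants(grid: int = 2001) -> tuple[float, float, float]:
    """Normalising constants making each surface attain a maximum of 10.

    Each constant is 10 divided by the maximum of the unnormalised surface
    over the unit square, located by a dense grid search and refined by a
    bounded local maximisation started at the grid argmax.
    """
    axis = np.linspace(0.0, 1.0, grid)
    g1, g2 = np.meshgrid(axis, axis)
    constants = []
    for sid in (1, 2, 3):
        vals = _surface_raw(sid, g1, g2)
        i = int(np.argmax(vals))
        x0 = np.array([g1.ravel()[i], g2.ravel()[i]])
        best = float(vals.ravel()[i])
        if sid != 3:  # surface 3's argmax sits on a discontinuity boundary
            res = optimize.minimize(
                lambda p, s=sid: -float(_surface_raw(s, p[0], p[1])),
                x0,
                bounds=[(0.0, 1.0), (0.0, 1.0)],
                method="L-BFGS-B",
            )
            best = max(best, -float(res.fun))
        constants.append(DEFAULT_L / best)
    return tuple(constants)


def eval_surface(surface_id: int, points: np.ndarray) -> np.ndarray:
    """Evaluate a canonical surface at points inside the unit square.

    Parameters
    ----------
    surface_id
        1, 2 or 3.
    points
        Array of shape ``(..., 2)`` or a single ``(2,)`` location.

    Returns
    -------
    Values in ``[0, 10]`` with shape ``points.shape[:-1]``.
    """
    p = np.asarray(points, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    if ((p < 0.0) | (p > 1.0)).any():
        raise ValueError("surface evaluation requires points in the unit square")
    C = derive_constants()[surface_id - 1]
    out = C * _surface_raw(surface_id, p[..., 0], p[..., 1])
    return float(out[0]) if scalar else out


def surface_function(surface_id: int) -> Callable[[np.ndarray], np.ndarray]:
    """The surface as a plain callable ``f(points) -> values``."""
    return lambda points: eval_surface(surface_id, points)


def continuous_population(surface_id: int) -> ContinuousPopulation:
    """Continuous population on the unit square generated by a surface."""
    return ContinuousPopulation(UNIT_SQUARE, surface_function(surface_id))


# ---------------------------------------------------------------------------
# Area populations
# ---------------------------------------------------------------------------

def make_area_population(
    surface_id: int, g: int, subgrid: int = 20
) -> AreaPopulation:
    """Partition the unit square into ``g x g`` quadrats with surface totals.

    The amount per quadrat is the numerical integral of the surface over the
    quadrat, computed by the midpoint rule on a ``subgrid x subgrid``
    refinement. The midpoint rule is exact for piecewise-constant fields and
    second-order accurate otherwise; for surface 3 the discontinuities align
    with quadrat edges for every even grid size used here, so no quadrat
    straddles a jump.
    """
    if g < 1:
        raise ValueError("grid side g must be >= 1")
    m = subgrid
    n = g * m
    axis = (np.arange(n) + 0.5) / n  # midpoints of the fine grid
    gx, gy = np.meshgrid(axis, axis)
    vals = eval_surface(surface_id, np.stack([gx, gy], axis=-1))
    # average the fine grid within each quadrat: rows index y, cols index x
    per_quadrat_mean = vals.reshape(g, m, g, m).mean(axis=(1, 3))
    cell_area = 1.0 / (g * g)
    totals = (per_quadrat_mean * cell_area).ravel()  # row-major from lower-left
    return AreaPopulation(UNIT_SQUARE, g, totals)


# ---------------------------------------------------------------------------
# Unit populations: spatial patterns
# ---------------------------------------------------------------------------

def _regular_locations(
    sizes: Sequence[int], rng: np.random.Generator, retry_cap: int
) -> np.ndarray:
    accepted = np.empty((sizes[-1], 2))
    count = 0
    for n_level in sizes:
        threshold = 0.5 * n_level ** -0.5
        while count < n_level:
            rejections = 0
            while True:
                proposal = rng.random(2)
                if count == 0:
                    break
                d2 = np.sum((accepted[:count] - proposal) ** 2, axis=1)
                if d2.min() >= threshold**2:
                    break
                rejections += 1
                if rejections > retry_cap:
                    raise RuntimeError(
                        f"regular pattern generation exceeded {retry_cap} "
                        f"consecutive rejections at level size {n_level}"
                    )
            accepted[count] = proposal
            count += 1
    return accepted


def _clustered_locations(
    sizes: Sequence[int],
    rng: np.random.Generator,
    n_clusters: int = 10,
    variance: float = 0.025,
) -> np.ndarray:
    increments = [sizes[0]] + [b - a for a, b in zip(sizes[:-1], sizes[1:])]
    if any(inc % n_clusters for inc in increments):
        raise ValueError(
            f"clustered pattern requires size increments divisible by {n_clusters}"
        )
    per_cluster = [inc // n_clusters for inc in increments]
    sd = math.sqrt(variance)
    centers = rng.random((n_clusters, 2))
    blocks = []
    for m in per_cluster:
        level_pts = np.empty((n_clusters * m, 2))
        k = 0
        for c in centers:
            got = 0
            while got < m:
                pts = c + sd * rng.standard_normal((m - got, 2))
                ok = pts[((pts >= 0.0) & (pts <= 1.0)).all(axis=1)]
                level_pts[k : k + len(ok)] = ok
                k += len(ok)
                got += len(ok)
        blocks.append(level_pts)
    return np.concatenate(blocks)


def generate_unit_pattern(
    pattern: str,
    sizes: Sequence[int] = (500, 1000, 1500),
    rng: np.random.Generator | None = None,
    retry_cap: int = 10_000,
) -> list[UnitPopulation]:
    """Generate a nested ladder of unit populations under a spatial pattern.

    Patterns
    --------
    regular
        Sequential uniform proposals, discarding any proposal nearer than
        ``0.5 * n_level**-0.5`` to every previously accepted point, with the
        threshold shrinking as each ladder level fills.
    random
        i.i.d. uniform locations; the first ``sizes[0]`` form level 1, etc.
    trended
        ``(1 - u1**2, 1 - u2**2)`` from independent uniforms, concentrating
        units toward the upper-right corner.
    clustered
        10 uniform cluster centres; each ladder level adds 50 points per
        cluster from a circular Gaussian (per-coordinate variance 0.025)
        centred on the cluster, redrawing points falling outside the square.

    Returns the populations in increasing size order; each level's locations
    are exactly a prefix of the next level's.
    """
    if pattern not in UNIT_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {UNIT_PATTERNS}")
    sizes = tuple(int(s) for s in sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])) or sizes[0] < 1:
        raise ValueError("sizes must be strictly increasing positive integers")
    rng = np.random.default_rng() if rng is None else rng

    if pattern == "regular":
        locations = _regular_locations(sizes, rng, retry_cap)
    elif pattern == "random":
        locations = rng.random((sizes[-1], 2))
    elif pattern == "trended":
        u = rng.random((sizes[-1], 2))
        locations = 1.0 - u**2
    else:  # clustered
        locations = _clustered_locations(sizes, rng)

    return [
        UnitPopulation(
            locations[:n].copy(), pattern=pattern, level=lvl + 1
        )
        for lvl, n in enumerate(sizes)
    ]


def assign_surface_values(pop: UnitPopulation, surface_id: int) -> UnitPopulation:
    """Attach survey-variable values read off a canonical surface."""
    return replace(pop, values=eval_surface(surface_id, pop.locations))


def truncate_units(pop: UnitPopulation, l: float) -> UnitPopulation:
    """Drop units whose value falls below the threshold ``l``.

    Retains exactly the units with ``y >= l``, preserving order (so nesting
    by prefix survives on the retained subsequence).
    """
    if pop.values is None:
        raise ValueError("population has no values to truncate on")
    if not 0 <= l < pop.L:
        raise ValueError("threshold must satisfy 0 <= l < L")
    keep = pop.values >= l
    if not keep.any():
        raise ValueError("truncation removed every unit in the population")
    return replace(
        pop,
        locations=pop.locations[keep],
        values=pop.values[keep],
        predictions=None if pop.predictions is None else pop.predictions[keep],
        pi=None if pop.pi is None else pop.pi[keep],
    )


def make_predictions(
    pop: UnitPopulation,
    rho: float = 0.10,
    L: float = DEFAULT_L,
    l: float = 4.0,
    L_star: float = 50.0,
) -> UnitPopulation:
    """Attach linear expert predictions and 3P inclusion probabilities.

    Predictions follow ``x = a + b*y`` with ``b = 1 - rho*(L + l)/(L - l)``
    and ``a = (1 + rho)*l - b*l``, so the relative prediction error is at most
    ``rho`` on ``[l, L]``, attained exactly at both extremes (over-prediction
    at ``y = l``, under-prediction at ``y = L``). Inclusion probabilities are
    ``pi = x / L_star``.
    """
    if pop.values is None:
        raise ValueError("population has no values")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if not l < L:
        raise ValueError("need l < L")
    y = pop.values
    if ((y < l - 1e-12) | (y > L + 1e-12)).any():
        raise ValueError("all values must lie in [l, L] for the prediction model")
    b = 1.0 - rho * (L + l) / (L - l)
    a = (1.0 + rho) * l - b * l
    x = a + b * y
    pi = x / L_star
    if (pi > 1.0).any() or (pi <= 0.0).any():
        raise ValueError("configuration yields inclusion probabilities outside (0, 1]")
    return replace(pop, predictions=x, pi=pi)


def threep_pi_floor(l: float, L_star: float) -> float:
    """Design floor for 3P inclusion probabilities: ``l / L_star``.

    Truncating the population at a value threshold ``l`` guarantees every
    prediction-based inclusion probability exceeds this closed-form bound.
    """
    return l / L_star
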