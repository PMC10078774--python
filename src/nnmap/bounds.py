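"""Finite-sample error bounds for the NN interpolator.

The design-based expected absolute interpolation error at a location ``p``
splits into a roughness term and a sampling term:

    E|f^(p) - f(p)|  <=  Delta(p, delta) + L * Pr{A(p, delta)},

where ``Delta(p, delta)`` is the largest jump of the field within the
``delta``-ball of ``p`` and ``A(p, delta)`` is the *miss event* that no
sampled location falls within that ball. The module computes oscillation
profiles, analytic miss probabilities for uniform random sampling (URS) and
tessellation stratified sampling (TSS) via exact circle-rectangle
intersection areas, Monte-Carlo miss probabilities for any scheme, the
pointwise bound above, a second-moment bound on the miss probability from
per-location and pairwise inclusion probabilities, the Lipschitz
``n**-1/2``-rate version of the bound, and a Monte-Carlo estimator of the
mean integrated absolute error (MIAE) of the whole map.

Conventions: the miss event uses the *strict* inequality ``|P_i - p| > delta``
(the ball is closed), so ``delta = 0`` makes the miss event almost sure under
continuous designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .interpolator import nn_values
from .populations import StudyRegion, UNIT_SQUARE, DEFAULT_L
from .sampling import (
    CONTINUOUS_SCHEMES,
    SchemeSpec,
    draw,
    draw_locations_many,
)

__all__ = [
    "OscillationProfile",
    "MissProbability",
    "MiaeEstimate",
    "circle_rect_area",
    "oscillation",
    "miss_prob_urs",
    "miss_prob_tss",
    "miss_prob_mc",
    "pointwise_error_bound",
    "miss_prob_pairwise_bound",
    "lipschitz_rate_bound",
    "miae_mc",
]


@dataclass(frozen=True)
class OscillationProfile:
    """Largest jump of the field within the ``delta``-ball of a location."""

    p: tuple[float, float]
    delta: float
    value: float
    resolution: int  # grid resolution at which the sup stabilised


@dataclass(frozen=True)
class MissProbability:
    """Probability that no sampled location lies within ``delta`` of ``p``."""

    p: tuple[float, float]
    delta: float
    n: int
    value: float
    method: str  # 'analytic' | 'mc'
    se: float | None = None


@dataclass(frozen=True)
class MiaeEstimate:
    """Monte-Carlo estimate of the mean integrated absolute error."""

    value: float
    se: float
    reps: int


# ---------------------------------------------------------------------------
# Exact circle-rectangle intersection area
# ---------------------------------------------------------------------------

def _antiderivative_halfchord(u: float, r: float) -> float:
    """Antiderivative of sqrt(r^2 - u^2)."""
    u = min(max(u, -r), r)
    return 0.5 * (u * math.sqrt(max(r * r - u * u, 0.0)) + r * r * math.asin(u / r))


def circle_rect_area(
    cx: float, cy: float, r: float,
    xmin: float, ymin: float, xmax: float, ymax: float,
) -> float:
    """Area of the intersection of a disc with an axis-aligned rectangle.

    Exact piecewise closed form: the 1-D integral over ``x`` of the clipped
    chord height is split at the abscissae where the circle crosses the
    rectangle's horizontal edges, and each piece is integrated analytically.
    """
    if r <= 0:
        return 0.0
    x0, x1 = xmin - cx, xmax - cx
    y0, y1 = ymin - cy, ymax - cy
    a, b = max(x0, -r), min(x1, r)
    if a >= b or y0 >= r or y1 <= -r:
        return 0.0
    cuts = {a, b}
    for yc in (y0, y1):
        if -r < yc < r:
            u = math.sqrt(r * r - yc * yc)
            for s in (-u, u):
                if a < s < b:
                    cuts.add(s)
    grid = sorted(cuts)
    area = 0.0
    for u0, u1 in zip(grid[:-1], grid[1:]):
        um = 0.5 * (u0 + u1)
        s = math.sqrt(max(r * r - um * um, 0.0))
        top_is_chord = s < y1
        bot_is_chord = -s > y0
        if min(y1, s) <= max(y0, -s):
            continue
        # integral of the top boundary
        if top_is_chord:
            top = _antiderivative_halfchord(u1, r) - _antiderivative_halfchord(u0, r)
        else:
            top = y1 * (u1 - u0)
        # integral of the bottom boundary
        if bot_is_chord:
            bot = -(_antiderivative_halfchord(u1, r) - _antiderivative_halfchord(u0, r))
        else:
            bot = y0 * (u1 - u0)
        area += top - bot
    return max(area, 0.0)


def _ball_region_area(region: StudyRegion, p: np.ndarray, delta: float) -> float:
    return circle_rect_area(
        p[0], p[1], delta, region.xmin, region.ymin, region.xmax, region.ymax
    )


# ---------------------------------------------------------------------------
# Oscillation
# ---------------------------------------------------------------------------

def oscillation(
    field: Callable[[np.ndarray], np.ndarray],
    p: np.ndarray,
    delta: float,
    region: StudyRegion = UNIT_SQUARE,
    resolution: int = 201,
    refine_tol: float = 1e-4,
    max_refinements: int = 5,
) -> OscillationProfile:
    """Largest jump ``sup_{|q-p|<=delta} |f(q) - f(p)|`` of the field.

    The supremum is approximated over a regular grid of the ``delta``-ball
    intersected with the region; the grid is repeatedly doubled until the
    estimate changes by less than ``refine_tol``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    p = np.asarray(p, dtype=float)
    fp = float(np.asarray(field(p[None, :])).ravel()[0])

    def estimate(res: int) -> float:
        xs = np.linspace(max(region.xmin, p[0] - delta), min(region.xmax, p[0] + delta), res)
        ys = np.linspace(max(region.ymin, p[1] - delta), min(region.ymax, p[1] + delta), res)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inside = ((pts - p) ** 2).sum(axis=1) <= delta * delta
        if not inside.any():
            return 0.0
        vals = np.asarray(field(pts[inside]))
        return float(np.abs(vals - fp).max())

    res = resolution
    best = estimate(res)
    for _ in range(max_refinements):
        res = 2 * res - 1
        new = estimate(res)
        done = abs(new - best) < refine_tol
        best = max(best, new)  # sup estimates only grow with refinement
        if done:
            break
    return OscillationProfile((float(p[0]), float(p[1])), delta, best, res)


# ---------------------------------------------------------------------------
# Miss probabilities
# ---------------------------------------------------------------------------

def miss_prob_urs(
    region: StudyRegion, p: np.ndarray, delta: float, n: int
) -> MissProbability:
    """Analytic miss probability under URS: ``(1 - lambda(ball & B)/lambda(B))**n``."""
    if delta < 0 or n < 1:
        raise ValueError("need delta >= 0 and n >= 1")
    p = np.asarray(p, dtype=float)
    frac = _ball_region_area(region, p, delta) / region.area
    return MissProbability(
        (float(p[0]), float(p[1])), delta, n, (1.0 - frac) ** n, "analytic"
    )


def miss_prob_tss(
    region: StudyRegion, p: np.ndarray, delta: float, k: int
) -> MissProbability:
    """Analytic miss probability under TSS: product over tessellation cells.

    Each cell contributes one independent uniform point, so the miss
    probability is the product of ``1 - lambda(ball & cell)/lambda(cell)``.
    For ``delta >= sqrt(2) * cellside`` some cell is fully covered by the
    ball and the product is exactly zero — the spatial-balance guarantee.
    """
    if delta < 0 or k < 1:
        raise ValueError("need delta >= 0 and k >= 1")
    p = np.asarray(p, dtype=float)
    w, h = region.width / k, region.height / k
    cell_area = w * h
    prob = 1.0
    for row in range(k):
        for col in range(k):
            x0 = region.xmin + col * w
            y0 = region.ymin + row * h
            a = circle_rect_area(p[0], p[1], delta, x0, y0, x0 + w, y0 + h)
            prob *= max(1.0 - a / cell_area, 0.0)
            if prob == 0.0:
                break
        if prob == 0.0:
            break
    return MissProbability((float(p[0]), float(p[1])), delta, k * k, prob, "analytic")


def miss_prob_mc(
    spec: SchemeSpec,
    population,
    p: np.ndarray,
    delta: float,
    reps: int,
    rng: np.random.Generator,
) -> MissProbability:
    """Monte-Carlo miss probability for any scheme.

    The miss event uses the strict inequality ``dist > delta``; in particular
    ``delta = 0`` misses almost surely under continuous designs.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    p = np.asarray(p, dtype=float)
    if spec.scheme in CONTINUOUS_SCHEMES:
        region = population if isinstance(population, StudyRegion) else UNIT_SQUARE
        locs = draw_locations_many(spec, region, reps, rng)
        d2min = ((locs - p) ** 2).sum(axis=2).min(axis=1)
        misses = d2min > delta * delta
        n = locs.shape[1]
    else:
        misses = np.empty(reps, dtype=bool)
        n = 0
        for r in range(reps):
            sample = draw(spec, population, rng)
            d2 = ((sample.locations - p) ** 2).sum(axis=1)
            misses[r] = d2.min() > delta * delta
            n = sample.n
    value = float(misses.mean())
    se = math.sqrt(value * (1.0 - value) / reps)
    return MissProbability((float(p[0]), float(p[1])), delta, n, value, "mc", se)


def _best_miss_prob(
    spec: SchemeSpec,
    population,
    p: np.ndarray,
    delta: float,
    rng: np.random.Generator | None,
    mc_reps: int,
) -> MissProbability:
    region = population if isinstance(population, StudyRegion) else UNIT_SQUARE
    if spec.scheme == "urs":
        return miss_prob_urs(region, p, delta, spec.n)
    if spec.scheme == "tss":
        return miss_prob_tss(region, p, delta, spec.k)
    if rng is None:
        raise ValueError(f"scheme {spec.scheme!r} needs an rng for MC miss probability")
    return miss_prob_mc(spec, population, p, delta, mc_reps, rng)


# ---------------------------------------------------------------------------
# Bounds
# ---------------------------------------------------------------------------

def pointwise_error_bound(
    field: Callable[[np.ndarray], np.ndarray],
    spec: SchemeSpec,
    population,
    p: np.ndarray,
    delta: float,
    L: float = DEFAULT_L,
    region: StudyRegion = UNIT_SQUARE,
    rng: np.random.Generator | None = None,
    mc_reps: int = 10_000,
) -> float:
    """Upper bound ``Delta(p, delta) + L * Pr{A(p, delta)}`` on ``E|f^(p)-f(p)|``.

    Uses the analytic miss probability for URS and TSS, Monte Carlo for any
    other scheme.
    """
    p = np.asarray(p, dtype=float)
    osc = oscillation(field, p, delta, region=region)
    miss = _best_miss_prob(spec, population, p, delta, rng, mc_reps)
    return osc.value + L * miss.value


def miss_prob_pairwise_bound(
    q: np.ndarray, joint: np.ndarray | None = None
) -> float:
    """Second-moment bound on the miss probability from inclusion structure.

    Given per-location hit probabilities ``q_i = Pr{|P_i - p| <= delta}`` and
    the pairwise joint hit probabilities, the probability that the ball
    catches no sampled location satisfies

        Pr{Z = 0} <= 1 / [ sum_i q_i + sup_{h != i} r_ih/(q_i q_h) - 1 ]_+

    where ``r_ih`` is the joint hit probability and the positive-part
    convention returns ``+inf`` (a vacuous bound) when the bracket is
    non-positive. Under independent selections the supremum equals one and
    the bound reduces to ``1 / (sum_i q_i)``.
    """
    q = np.asarray(q, dtype=float)
    if (q <= 0).any():
        raise ValueError("all hit probabilities must be positive")
    n = len(q)
    if joint is None:
        sup_ratio = 1.0  # independence
    else:
        joint = np.asarray(joint, dtype=float)
        if joint.shape != (n, n):
            raise ValueError("joint must be an (n, n) matrix")
        ratio = joint / np.outer(q, q)
        off = ~np.eye(n, dtype=bool)
        sup_ratio = float(ratio[off].max()) if n > 1 else 1.0
    bracket = float(q.sum()) + sup_ratio - 1.0
    return math.inf if bracket <= 0 else 1.0 / bracket


def lipschitz_rate_bound(
    beta: float,
    t: float,
    n: int,
    spec: SchemeSpec,
    population,
    p: np.ndarray,
    L: float = DEFAULT_L,
    rng: np.random.Generator | None = None,
    mc_reps: int = 10_000,
) -> float:
    """Rate-form bound ``beta*t*n**-1/2 + L*Pr{A(p, t*n**-1/2)}``.

    For a ``beta``-Lipschitz field the oscillation term is at most
    ``beta * delta``; choosing ``delta = t * n**-1/2`` exposes the
    ``n**-1/2`` consistency rate: under TSS with ``t >= sqrt(2)`` (cell-side
    units) the miss term vanishes identically.
    """
    if beta < 0 or t <= 0 or n < 1:
        raise ValueError("need beta >= 0, t > 0, n >= 1")
    delta = t / math.sqrt(n)
    p = np.asarray(p, dtype=float)
    miss = _best_miss_prob(spec, population, p, delta, rng, mc_reps)
    return beta * delta + L * miss.value


# ---------------------------------------------------------------------------
# Mean integrated absolute error
# ---------------------------------------------------------------------------

def miae_mc(
    field: Callable[[np.ndarray], np.ndarray],
    spec: SchemeSpec,
    reps: int,
    rng: np.random.Generator,
    region: StudyRegion = UNIT_SQUARE,
    grid_res: int = 100,
) -> MiaeEstimate:
    """Monte-Carlo estimate of the mean integrated absolute error of the map.

    Each replication draws a sample, builds the NN map on a regular
    ``grid_res x grid_res`` quadrature grid, and integrates ``|f^ - f|`` by
    the midpoint rule; the estimate averages over replications.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if spec.scheme not in CONTINUOUS_SCHEMES:
        raise ValueError("MIAE is defined for continuous-region schemes here")
    xs = (np.arange(grid_res) + 0.5) / grid_res * region.width + region.xmin
    ys = (np.arange(grid_res) + 0.5) / grid_res * region.height + region.ymin
    gx, gy = np.meshgrid(xs, ys)
    support = np.column_stack([gx.ravel(), gy.ravel()])
    truth = np.asarray(field(support))
    locs = draw_locations_many(spec, region, reps, rng)
    per_rep = np.empty(reps)
    for r in range(reps):
        vals = np.asarray(field(locs[r]))
        est = nn_values(locs[r], vals, support)
        per_rep[r] = np.abs(est - truth).mean() * region.area
    value = float(per_rep.mean())
    se = float(per_rep.std(ddof=1) / math.sqrt(reps)) if reps > 1 else math.nan
    return MiaeEstimate(value, se, reps)
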