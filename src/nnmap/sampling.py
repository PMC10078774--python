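"""Probabilistic sampling schemes for spatial populations.

All schemes share one :class:`SchemeSpec` descriptor so the exact design used
to select an original sample can be replayed verbatim by the pseudopopulation
bootstrap. Continuous-region schemes (URS, TSS, SGS) additionally expose a
batched draw used by Monte-Carlo loops.

Schemes
-------
urs
    Uniform random sampling: ``n`` i.i.d. uniform locations.
tss
    Tessellation stratified sampling: the region is split into a ``k x k``
    grid of equal quadrats and one uniform location is drawn per quadrat
    independently (``n = k**2``).
sgs
    Systematic grid sampling: a single uniform within-cell offset translated
    to every quadrat of the ``k x k`` tessellation (aligned systematic grid).
srswor
    Simple random sampling without replacement of ``n`` of ``N`` areas/units.
opss
    One-per-stratum stratified sampling: the population grid is tiled by
    blocks of contiguous quadrats (default 2 rows x 5 columns) and one
    quadrat is selected uniformly and independently per block.
sys
    Systematic sampling: one within-block position drawn uniformly once and
    replicated across all blocks.
threep
    Probability-proportional-to-prediction Poisson sampling: each unit enters
    independently with probability ``pi_j = x_j / L*``; the realised size is
    random.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from .populations import AreaPopulation, StudyRegion, UnitPopulation

__all__ = [
    "SchemeSpec",
    "SampleRealization",
    "draw",
    "draw_urs",
    "draw_tss",
    "draw_sgs",
    "draw_srswor",
    "draw_opss",
    "draw_sys_blocks",
    "draw_threep",
    "draw_locations_many",
]

CONTINUOUS_SCHEMES = ("urs", "tss", "sgs")
FINITE_SCHEMES = ("srswor", "opss", "sys")


@dataclass(frozen=True)
class SchemeSpec:
    """Descriptor of a sampling design, reusable for bootstrap resampling."""

    scheme: str
    n: int | None = None  # urs / srswor sample size
    k: int | None = None  # tessellation side for tss / sgs
    block_shape: tuple[int, int] = (2, 5)  # (grid rows, grid cols) per block
    L_star: float = 50.0  # 3P normalising constant

    def __post_init__(self) -> None:
        known = CONTINUOUS_SCHEMES + FINITE_SCHEMES + ("threep",)
        if self.scheme not in known:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {known}")
        if self.scheme in ("tss", "sgs") and (self.k is None or self.k < 1):
            raise ValueError(f"{self.scheme} requires tessellation side k >= 1")
        if self.scheme in ("urs", "srswor") and (self.n is None or self.n < 1):
            raise ValueError(f"{self.scheme} requires sample size n >= 1")

    @property
    def sample_size(self) -> int | None:
        """Fixed sample size, when the scheme has one (None for 3P)."""
        if self.scheme in ("tss", "sgs"):
            return self.k * self.k
        return self.n

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SchemeSpec":
        d: dict[str, Any] = json.loads(text)
        if "block_shape" in d and d["block_shape"] is not None:
            d["block_shape"] = tuple(d["block_shape"])
        return cls(**d)


@dataclass(frozen=True)
class SampleRealization:
    """One realised sample: locations, observed values, and frame extras."""

    locations: np.ndarray  # (n, 2)
    values: np.ndarray | None = None  # observed f(P_i)
    indices: np.ndarray | None = None  # selected indices for finite settings
    predictions: np.ndarray | None = None  # x_j of sampled units (3P)
    pi: np.ndarray | None = None  # inclusion probabilities of sampled units
    spec: SchemeSpec | None = None

    @property
    def n(self) -> int:
        return len(self.locations)

    @property
    def residuals(self) -> np.ndarray:
        """Observed prediction errors ``e_i = y_i - x_i`` (3P samples)."""
        if self.values is None or self.predictions is None:
            raise ValueError("residuals require both values and predictions")
        return self.values - self.predictions


# ---------------------------------------------------------------------------
# Continuous-region schemes
# ---------------------------------------------------------------------------

def _scale_to_region(u: np.ndarray, region: StudyRegion) -> np.ndarray:
    out = np.empty_like(u)
    out[..., 0] = region.xmin + u[..., 0] * region.width
    out[..., 1] = region.ymin + u[..., 1] * region.height
    return out


def _cell_origins(region: StudyRegion, k: int) -> np.ndarray:
    """Lower-left corners of the k x k tessellation, row-major, shape (k*k, 2)."""
    w, h = region.width / k, region.height / k
    cols, rows = np.meshgrid(np.arange(k), np.arange(k))
    return np.column_stack(
        [region.xmin + cols.ravel() * w, region.ymin + rows.ravel() * h]
    )


def draw_urs(
    region: StudyRegion, n: int, rng: np.random.Generator
) -> SampleRealization:
    """Uniform random sampling of ``n`` independent locations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u = rng.random((n, 2))
    return SampleRealization(_scale_to_region(u, region), spec=SchemeSpec("urs", n=n))


def draw_tss(
    region: StudyRegion, k: int, rng: np.random.Generator
) -> SampleRealization:
    """Tessellation stratified sampling: one uniform location per quadrat."""
    origins = _cell_origins(region, k)
    u = rng.random((k * k, 2))
    w, h = region.width / k, region.height / k
    pts = origins + u * np.array([w, h])
    return SampleRealization(pts, spec=SchemeSpec("tss", k=k))


def draw_sgs(
    region: StudyRegion, k: int, rng: np.random.Generator
) -> SampleRealization:
    """Systematic grid sampling: one shared offset replicated in every quadrat."""
    origins = _cell_origins(region, k)
    u = rng.random(2)
    w, h = region.width / k, region.height / k
    pts = origins + u * np.array([w, h])
    return SampleRealization(pts, spec=SchemeSpec("sgs", k=k))


def draw_locations_many(
    spec: SchemeSpec, region: StudyRegion, reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Batched draws for continuous schemes: shape ``(reps, n, 2)``.

    Statistically identical to ``reps`` independent single draws; used by
    Monte-Carlo estimators and the bootstrap inner loop.
    """
    if spec.scheme == "urs":
        u = rng.random((reps, spec.n, 2))
        return _scale_to_region(u, region)
    if spec.scheme in ("tss", "sgs"):
        k = spec.k
        origins = _cell_origins(region, k)  # (k*k, 2)
        wh = np.array([region.width / k, region.height / k])
        if spec.scheme == "tss":
            u = rng.random((reps, k * k, 2))
        else:
            u = rng.random((reps, 1, 2))
        return origins[None, :, :] + u * wh
    raise ValueError(f"batched draws are only defined for {CONTINUOUS_SCHEMES}")


# ---------------------------------------------------------------------------
# Finite-population schemes
# ---------------------------------------------------------------------------

def draw_srswor(N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` distinct indices uniformly over subsets of ``{0, ..., N-1}``."""
    if not 1 <= n <= N:
        raise ValueError("need 1 <= n <= N")
    return np.sort(rng.choice(N, size=n, replace=False))


def _block_layout(g: int, block_shape: tuple[int, int]) -> tuple[int, int]:
    br, bc = block_shape
    if g % br or g % bc:
        raise ValueError(
            f"block shape {block_shape} does not tile a {g}x{g} grid exactly"
        )
    return br, bc


def _block_selection(
    g: int, block_shape: tuple[int, int], within: np.ndarray
) -> np.ndarray:
    """Row-major quadrat indices given per-block within-block (row, col) picks."""
    br, bc = block_shape
    nbr, nbc = g // br, g // bc
    block_rows, block_cols = np.meshgrid(np.arange(nbr), np.arange(nbc), indexing="ij")
    rows = block_rows.ravel() * br + within[:, 0]
    cols = block_cols.ravel() * bc + within[:, 1]
    return np.sort(rows * g + cols)


def draw_opss(
    g: int, block_shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """One-per-stratum stratified sampling over a ``g x g`` quadrat grid."""
    br, bc = _block_layout(g, block_shape)
    n_blocks = (g // br) * (g // bc)
    within = np.column_stack(
        [rng.integers(0, br, n_blocks), rng.integers(0, bc, n_blocks)]
    )
    return _block_selection(g, block_shape, within)


def draw_sys_blocks(
    g: int, block_shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Systematic sampling: one within-block offset replicated across blocks."""
    br, bc = _block_layout(g, block_shape)
    n_blocks = (g // br) * (g // bc)
    offset = np.array([rng.integers(0, br), rng.integers(0, bc)])
    within = np.broadcast_to(offset, (n_blocks, 2))
    return _block_selection(g, block_shape, within)


def draw_threep(
    pop: UnitPopulation,
    rng: np.random.Generator,
    max_redraws: int = 1000,
) -> SampleRealization:
    """3P (probability-proportional-to-prediction) Poisson sampling.

    Units enter independently with their frame probabilities ``pi_j``; the
    realised sample size is random. An empty realisation (possible but rare
    once probabilities are floored by value truncation) is redrawn with a
    warning, since an empty sample leaves the interpolator undefined.
    """
    if pop.pi is None:
        raise ValueError("population carries no inclusion probabilities")
    for attempt in range(max_redraws + 1):
        keep = rng.random(pop.N) < pop.pi
        if keep.any():
            break
        if attempt == 0:
            warnings.warn("empty 3P sample; redrawing", stacklevel=2)
    else:
        raise RuntimeError(f"3P sampling produced {max_redraws} empty samples")
    idx = np.flatnonzero(keep)
    return SampleRealization(
        locations=pop.locations[idx],
        values=None if pop.values is None else pop.values[idx],
        indices=idx,
        predictions=None if pop.predictions is None else pop.predictions[idx],
        pi=pop.pi[idx],
        spec=SchemeSpec("threep", L_star=50.0),
    )


# ---------------------------------------------------------------------------
# Unified dispatcher
# ---------------------------------------------------------------------------

def draw(
    spec: SchemeSpec,
    population: StudyRegion | AreaPopulation | UnitPopulation,
    rng: np.random.Generator,
) -> SampleRealization:
    """Draw one sample under ``spec`` from a region or finite population.

    For continuous schemes ``population`` is a :class:`StudyRegion` (values
    are not observed here; callers evaluate the field at the returned
    locations). For finite schemes the realisation carries selected indices,
    centroids/locations, and observed values.
    """
    if spec.scheme in CONTINUOUS_SCHEMES:
        if not isinstance(population, StudyRegion):
            raise TypeError(f"{spec.scheme} samples locations from a StudyRegion")
        if spec.scheme == "urs":
            out = draw_urs(population, spec.n, rng)
        elif spec.scheme == "tss":
            out = draw_tss(population, spec.k, rng)
        else:
            out = draw_sgs(population, spec.k, rng)
        return SampleRealization(out.locations, spec=spec)

    if spec.scheme in FINITE_SCHEMES:
        if isinstance(population, AreaPopulation):
            N, locs, vals = population.N, population.centroids, population.densities
            g = population.g
        elif isinstance(population, UnitPopulation):
            if population.values is None:
                raise ValueError("unit population has no values")
            N, locs, vals = population.N, population.locations, population.values
            g = None
        else:
            raise TypeError(f"{spec.scheme} requires a finite population")
        if spec.scheme == "srswor":
            idx = draw_srswor(N, spec.n, rng)
        else:
            if g is None:
                raise TypeError("block schemes require a gridded area population")
            if spec.scheme == "opss":
                idx = draw_opss(g, spec.block_shape, rng)
            else:
                idx = draw_sys_blocks(g, spec.block_shape, rng)
        return SampleRealization(locs[idx], values=vals[idx], indices=idx, spec=spec)

    # threep
    if not isinstance(population, UnitPopulation):
        raise TypeError("3P sampling requires a unit population")
    out = draw_threep(population, rng)
    return SampleRealization(
        out.locations, out.values, out.indices, out.predictions, out.pi, spec=spec
    )
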