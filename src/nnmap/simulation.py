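"""Monte-Carlo evaluation of NN mapping error and its bootstrap estimator.

For a population x scheme x size configuration the harness replicates the
whole survey ``R`` times: draw a sample, build the NN map, optionally run an
``M``-sample pseudopopulation bootstrap, and accumulate per-support-point
error moments. It reports the absolute bias ``|mean error|``, the RMSE, and
the ratio of the mean bootstrap RMSE to the Monte-Carlo RMSE, together with
min/avg/max summaries over the support — the standard performance indicators
for design-based map evaluation.

Seeding: every replication gets an independent generator keyed by
``(master seed, configuration hash, replication index)``, so configurations
are individually reproducible and order-independent.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_rmse, threep_bootstrap_rmse
from .interpolator import nn_interpolate, nn_map_areas, residual_interpolate
from .populations import (
    UNIT_SQUARE,
    UnitPopulation,
    assign_surface_values,
    generate_unit_pattern,
    make_area_population,
    make_predictions,
    surface_function,
    truncate_units,
)
from .sampling import SampleRealization, SchemeSpec, draw

__all__ = [
    "McConfig",
    "McSummary",
    "StudyResult",
    "run_replications",
    "ratio_table",
    "full_study",
    "expected_sampling_fraction",
    "grid_support",
]

_LADDER = (500, 1000, 1500)  # canonical unit-population size ladder


def grid_support(resolution: int, region=UNIT_SQUARE) -> np.ndarray:
    """Cell-centre evaluation grid, row-major from the lower-left corner."""
    xs = region.xmin + (np.arange(resolution) + 0.5) / resolution * region.width
    ys = region.ymin + (np.arange(resolution) + 0.5) / resolution * region.height
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class McConfig:
    """One Monte-Carlo configuration: population, design and budgets."""

    setting: str  # 'continuous' | 'areas' | 'units'
    surface_id: int
    spec: SchemeSpec
    R: int
    M: int = 0  # bootstrap samples per replication; 0 disables the bootstrap
    eval_grid: int = 100  # continuous-setting evaluation resolution
    g: int | None = None  # areas: quadrat grid side
    pattern: str = "random"  # units: spatial pattern
    size: int = 500  # units: ladder level size before truncation
    rho: float = 0.10
    l: float = 4.0
    L_star: float = 50.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.R < 1 or self.M < 0:
            raise ValueError("need R >= 1 and M >= 0")
        compatible = {
            "continuous": ("urs", "tss", "sgs"),
            "areas": ("srswor", "opss", "sys"),
            "units": ("threep",),
        }
        if self.setting not in compatible:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.spec.scheme not in compatible[self.setting]:
            raise ValueError(
                f"scheme {self.spec.scheme!r} is incompatible with "
                f"setting {self.setting!r}"
            )
        if self.setting == "areas" and self.g is None:
            raise ValueError("area configurations require the grid side g")

    @property
    def label(self) -> str:
        size = {
            "continuous": f"n{self.spec.sample_size}",
            "areas": f"N{self.g * self.g}" if self.g else "",
            "units": f"{self.pattern}{self.size}",
        }[self.setting]
        return f"{self.setting}/s{self.surface_id}/{self.spec.scheme}/{size}"

    def _hash(self) -> int:
        key = f"{self.label}|{self.spec.to_json()}|{self.R}|{self.M}|{self.eval_grid}"
        return zlib.crc32(key.encode())


@dataclass(frozen=True)
class McSummary:
    """Per-point indicators and min/avg/max summaries for one configuration."""

    support: np.ndarray
    abs_bias: np.ndarray
    rmse: np.ndarray
    mean_rmse_star: np.ndarray | None
    config: McConfig
    ratio_undefined: int = 0  # support points with zero Monte-Carlo RMSE

    @property
    def variance(self) -> np.ndarray:
        return self.rmse**2 - self.abs_bias**2

    @property
    def ratio(self) -> np.ndarray | None:
        """mean(rmse*)/RMSE per point; NaN where the RMSE is exactly zero."""
        if self.mean_rmse_star is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.rmse > 0, self.mean_rmse_star / self.rmse, np.nan)
        return r

    def table(self) -> pd.DataFrame:
        """Indicator x (min, avg, max) summary table."""
        rows = {}
        rows["abs_bias"] = [self.abs_bias.min(), self.abs_bias.mean(), self.abs_bias.max()]
        rows["rmse"] = [self.rmse.min(), self.rmse.mean(), self.rmse.max()]
        ratio = self.ratio
        if ratio is not None:
            ok = ~np.isnan(ratio)
            if ok.any():
                rows["ratio"] = [ratio[ok].min(), ratio[ok].mean(), ratio[ok].max()]
            else:
                rows["ratio"] = [np.nan, np.nan, np.nan]
        return pd.DataFrame(rows, index=["min", "avg", "max"]).T


@dataclass(frozen=True)
class StudyResult:
    """Output of a full study: one summary per configuration plus frame facts."""

    summaries: dict[str, McSummary] = field(default_factory=dict)
    threep_sampling_fractions: dict[str, float] = field(default_factory=dict)


def _build_unit_population(config: McConfig, rng: np.random.Generator) -> UnitPopulation:
    sizes = _LADDER if config.size in _LADDER else (config.size,)
    ladder = generate_unit_pattern(config.pattern, sizes, rng)
    pop = ladder[sizes.index(config.size)]
    pop = assign_surface_values(pop, config.surface_id)
    pop = truncate_units(pop, config.l)
    return make_predictions(pop, config.rho, pop.L, config.l, config.L_star)


def run_replications(config: McConfig) -> McSummary:
    """Run the full replication loop for one configuration."""
    cfg_hash = config._hash()
    field_fn = surface_function(config.surface_id)

    if config.setting == "continuous":
        support = grid_support(config.eval_grid)
        truth = field_fn(support)
    elif config.setting == "areas":
        area_pop = make_area_population(config.surface_id, config.g)
        support = area_pop.centroids
        truth = area_pop.densities
    else:
        pop_rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, cfg_hash, 2**20])
        )
        unit_pop = _build_unit_population(config, pop_rng)
        support = unit_pop.locations
        truth = unit_pop.values

    nq = len(support)
    sum_e = np.zeros(nq)
    sum_e2 = np.zeros(nq)
    sum_rs = np.zeros(nq) if config.M else None

    for r in range(config.R):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.master_seed, cfg_hash, r])
        )
        if config.setting == "continuous":
            sample = draw(config.spec, UNIT_SQUARE, rng)
            sample = SampleRealization(
                sample.locations, values=field_fn(sample.locations), spec=config.spec
            )
            est = nn_interpolate(sample, support)
        elif config.setting == "areas":
            sample = draw(config.spec, area_pop, rng)
            est = nn_map_areas(sample, area_pop)
        else:
            sample = draw(config.spec, unit_pop, rng)
            est = residual_interpolate(sample, unit_pop)
        e = est.values - truth
        sum_e += e
        sum_e2 += e * e
        if config.M:
            if config.setting == "units":
                report = threep_bootstrap_rmse(est, unit_pop, config.M, rng)
            else:
                report = bootstrap_rmse(est, config.spec, config.M, rng)
            sum_rs += report.rmse_star

    mean_e = sum_e / config.R
    rmse = np.sqrt(sum_e2 / config.R)
    mean_rs = sum_rs / config.R if config.M else None
    undefined = int((rmse == 0).sum()) if config.M else 0
    if undefined:
        warnings.warn(
            f"{undefined} support points have zero Monte-Carlo RMSE; "
            "their bootstrap ratios are reported as NaN",
            stacklevel=2,
        )
    return McSummary(support, np.abs(mean_e), rmse, mean_rs, config, undefined)


def ratio_table(config: McConfig) -> McSummary:
    """Replication run with the bootstrap enabled (ratio rows populated)."""
    if config.M < 1:
        raise ValueError("ratio tables require M >= 1 bootstrap samples")
    return run_replications(config)


def expected_sampling_fraction(
    surface_id: int,
    rng: np.random.Generator,
    pattern: str = "random",
    size: int = 1500,
    rho: float = 0.10,
    l: float = 4.0,
    L_star: float = 50.0,
) -> float:
    """Mean 3P inclusion probability of a generated unit population.

    This is the expected sampling fraction of the design: units are included
    independently with ``pi_j = x_j / L*``, so the expected sample size is
    ``sum_j pi_j`` and the expected fraction is ``mean(pi_j)``.
    """
    sizes = _LADDER if size in _LADDER else (size,)
    ladder = generate_unit_pattern(pattern, sizes, rng)
    pop = ladder[sizes.index(size)]
    pop = assign_surface_values(pop, surface_id)
    pop = truncate_units(pop, l)
    pop = make_predictions(pop, rho, pop.L, l, L_star)
    return float(pop.pi.mean())


def _preset_parameters(preset: str) -> dict:
    if preset == "paper":
        warnings.warn(
            "the 'paper' preset replicates at full scale (R=10000, M=1000); "
            "expect cluster-scale runtimes",
            stacklevel=3,
        )
        return dict(
            R=10_000, M=1000, eval_grid=100,
            k_ladder=(4, 6, 8, 10), g_ladder=(10, 20, 30, 40),
            unit_sizes=(500, 1000, 1500),
        )
    if preset == "desk":
        return dict(
            R=500, M=100, eval_grid=25,
            k_ladder=(4, 6), g_ladder=(10, 20),
            unit_sizes=(500, 1000),
        )
    raise ValueError(f"unknown preset {preset!r} (expected 'paper' or 'desk')")


def full_study(
    preset: str = "desk",
    seed: int = 0,
    settings: Iterable[str] = ("continuous", "areas", "units"),
    surfaces: Iterable[int] = (1, 2, 3),
    R: int | None = None,
    M: int | None = None,
    eval_grid: int | None = None,
) -> StudyResult:
    """Run the whole population x scheme x size study at a preset scale.

    The ``paper`` preset uses the full replication budgets (R=10000, M=1000)
    and all four sizes per ladder; the ``desk`` preset uses R=500, M=100, the
    two smallest sizes per ladder, and a coarser continuous evaluation grid,
    which keeps any single configuration within a few minutes on one CPU.
    ``R``, ``M`` and ``eval_grid`` override the preset budgets when given.
    """
    par = _preset_parameters(preset)
    if R is not None:
        par["R"] = R
    if M is not None:
        par["M"] = M
    if eval_grid is not None:
        par["eval_grid"] = eval_grid
    result = StudyResult()
    settings = tuple(settings)

    for sid in surfaces:
        if "continuous" in settings:
            for scheme in ("urs", "tss", "sgs"):
                for k in par["k_ladder"]:
                    spec = (
                        SchemeSpec("urs", n=k * k)
                        if scheme == "urs"
                        else SchemeSpec(scheme, k=k)
                    )
                    cfg = McConfig(
                        "continuous", sid, spec, R=par["R"], M=par["M"],
                        eval_grid=par["eval_grid"], master_seed=seed,
                    )
                    result.summaries[cfg.label] = run_replications(cfg)
        if "areas" in settings:
            for scheme in ("srswor", "opss", "sys"):
                for g in par["g_ladder"]:
                    spec = (
                        SchemeSpec("srswor", n=g * g // 10)
                        if scheme == "srswor"
                        else SchemeSpec(scheme)
                    )
                    cfg = McConfig(
                        "areas", sid, spec, R=par["R"], M=par["M"], g=g,
                        master_seed=seed,
                    )
                    result.summaries[cfg.label] = run_replications(cfg)
        if "units" in settings:
            frac_rng = np.random.default_rng(
                np.random.SeedSequence([seed, sid, 2**21])
            )
            result.threep_sampling_fractions[f"s{sid}"] = expected_sampling_fraction(
                sid, frac_rng
            )
            for pattern in ("regular", "random", "trended", "clustered"):
                for size in par["unit_sizes"]:
                    cfg = McConfig(
                        "units", sid, SchemeSpec("threep"), R=par["R"], M=par["M"],
                        pattern=pattern, size=size, master_seed=seed,
                    )
                    result.summaries[cfg.label] = run_replications(cfg)
    return result
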