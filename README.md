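# nnmap — design-based nearest-neighbor spatial mapping

`nnmap` builds maps of a survey variable over a study region from a
probability sample of field observations, using the nearest-neighbor (NN)
interpolation rule, and — unusually for NN mapping, which is mostly used as a
purely descriptive technique — attaches design-based uncertainty to the
result. It is aimed at environmental, forest and ecological surveys where
the population is fixed and all randomness comes from the sampling scheme
that selected the observation locations (design-based inference under infill
asymptotics).

## The estimator

Given sampled locations P_1, …, P_n with observed values f(P_1), …, f(P_n),
the NN interpolator at a location p is

    f^(p) = f(P_i)   where  ‖P_i − p‖ = min_h ‖P_h − p‖,

with exact ties averaged (the tie set H_p). The map is piecewise constant on
the Voronoi cells of the sample; for finite populations of areas or point
units the same rule runs over area centroids or unit locations. The package
covers:

- **Populations** — continuous fields, gridded area populations, and point
  unit populations (with nested regular / random / trended / clustered
  synthetic patterns and three benchmark surfaces bounded by L = 10).
- **Sampling schemes** — uniform random (URS), tessellation stratified (TSS),
  systematic grid (SGS) for continuous regions; SRSWOR, one-per-stratum
  stratified (OPSS) and systematic (SYS) block sampling for area grids; and
  3P (probability-proportional-to-prediction) Poisson sampling for unit
  frames, with the residual-interpolation workflow y^_j = x_j + ê_j.
- **Error bounds** — the pointwise bound
  E|f^(p) − f(p)| ≤ Δ(p, δ) + L·Pr{A(p, δ)}, where Δ is the largest jump of
  f in the δ-ball and A(p, δ) the event that the sample misses that ball;
  analytic miss probabilities for URS/TSS via exact circle–rectangle
  geometry, Monte-Carlo ones for any scheme; and the mean integrated
  absolute error (MIAE) of whole maps.
- **Uncertainty** — a pseudopopulation bootstrap RMSE estimator: the
  estimated map is treated as a surrogate population, resampled M times with
  the original design, and rmse*(p) = ( (1/M) Σ_m (f^*_m(p) − f^(p))² )^1/2.
  Under spatial-balance and smoothness conditions its expectation is at most
  3× the true RMSE (conservative, typically 1.2–1.6 in practice).
- **Monte-Carlo harness** — per-location absolute bias, RMSE and
  bootstrap-ratio tables with min/avg/max summaries across population ×
  scheme × size grids.

## Worked example

Map benchmark surface 1 from a 6×6 tessellation stratified sample and
estimate the mapping uncertainty:

```python
import numpy as np
from nnmap import (UNIT_SQUARE, SampleRealization, SchemeSpec,
                   eval_surface, nn_interpolate, bootstrap_rmse, draw)
from nnmap.simulation import grid_support

rng = np.random.default_rng(42)
spec = SchemeSpec("tss", k=6)                      # one point per cell, n = 36
s = draw(spec, UNIT_SQUARE, rng)
sample = SampleRealization(s.locations, values=eval_surface(1, s.locations),
                           spec=spec)

support = grid_support(50)                         # 50×50 evaluation grid
est = nn_interpolate(sample, support, grid_shape=(50, 50))
truth = eval_surface(1, support)
print("map range: [%.3f, %.3f]" % (est.values.min(), est.values.max()))
print("mean |error| = %.4f" % np.abs(est.values - truth).mean())

report = bootstrap_rmse(est, spec, M=1000, rng=rng)
print("bootstrap rmse*: mean %.4f, max %.4f"
      % (report.rmse_star.mean(), report.rmse_star.max()))
```

Output:

```
map range: [1.841, 9.610]
mean |error| = 0.3211
bootstrap rmse*: mean 0.5173, max 1.4679
```

The map honours the observed range (NN values are always observed values),
the average absolute mapping error of the 36-point sample is ≈ 0.32 on a
field spanning [0, 10], and the bootstrap uncertainty map estimates the
per-cell RMSE without ever using the true surface — its mean (0.52) sits
above the realised error level, reflecting the estimator's deliberate
conservativeness.

The same workflow runs from the shell on user-supplied point files, e.g. a
forest / not-forest (0/1) survey:

```sh
nnmap interpolate --points sample.csv --grid 100 --region 0,0,7000,7000 --out forest.asc
nnmap bootstrap --points sample.csv --scheme tss --k 35 --m 1000 \
      --grid 100 --region 0,0,7000,7000 --seed 1 --out-prefix forest
nnmap simulate --preset desk --seed 1 --out study/
```

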