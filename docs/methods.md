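# Methods

## Setting and estimator

The package works in the design-based paradigm: the population is a fixed,
bounded function f with values in [0, L] on a rectangular study region B,
and all probability statements refer to the sampling scheme that selects the
observation support. Three population types share one estimator:

- *continuous*: f is a density observable at any location of B;
- *areas*: B is partitioned into a g×g grid of quadrats, each carrying a
  total y_j, observed as the per-area density y_j/λ(a_j) and located at its
  centroid;
- *units*: B is a finite set of N point units with values y_j ∈ [0, L].

The NN interpolator assigns to each evaluation point the observed value at
its nearest sampled location, averaging over exact ties. A query within
`tie_tol` of a sampled location returns that observation; membership in the
tie set uses the same tolerance (default 1e-9 in region units — exact ties
only arise on lattices, where symmetric distances are exactly equal in
floating point, and the tolerance guards quantisation noise). Distances are
Euclidean. Results are contractually independent of the search structure: a
vectorised full scan serves small samples, a k-d tree larger ones, and the
test-suite pins both to a literal per-query oracle.

The inverse-distance-weighting interpolator with weights ‖P_i − p‖^(−α) is
included because the NN rule is its α → ∞ limit; the suite uses α = 200 as
an independent cross-check on instances whose nearest sample point is an
isolated minimiser (at finite α near-ties cannot be resolved).

## Error bounds

For δ > 0 let Δ(p, δ) be the largest jump of f in the closed δ-ball of p and
A(p, δ) the event that no sampled location falls in that ball (strict
inequality ‖P_i − p‖ > δ; hence δ = 0 misses almost surely under continuous
designs). The pointwise bound

    E|f^(p) − f(p)| ≤ Δ(p, δ) + L · Pr{A(p, δ)}

separates roughness from design quality. Miss probabilities are computed
analytically for URS, (1 − λ(ball ∩ B)/λ(B))^n, and TSS, the product of the
per-cell complements — both via an exact piecewise closed form for the
circle–rectangle intersection area (1-D integration of the clipped chord
height, split at the abscissae where the circle crosses the rectangle's
horizontal edges; validated against grid quadrature). Any other scheme uses
a Monte-Carlo estimate with its binomial standard error.

A second-moment bound converts per-location and pairwise hit probabilities
into a bound on Pr{no hit}: 1/[Σ_i q_i + sup_{h≠i} r_ih/(q_i q_h) − 1]_+,
with +∞ returned when the bracket is non-positive (vacuous). Under
independence the supremum is 1 and the bound is 1/Σ q_i; the suite checks it
against the exact product Π(1 − q_i) on enumerable configurations.

For a β-Lipschitz field, choosing δ = t·n^(−1/2) yields the rate form
βt·n^(−1/2) + L·Pr{A(p, t·n^(−1/2))}. TSS and SGS ensure Pr{A(p, √2/k)} = 0
for every location — a cell of side 1/k around any point is fully covered —
so under them the miss term vanishes at t = √2 and the error is O(n^(−1/2)).
The oscillation Δ(p, δ) is approximated on a regular grid of the ball ∩ B,
doubled until the estimate moves by less than 1e-4 (the sup over a grid only
grows under refinement, so the iterate is kept monotone).

Map-level accuracy uses the mean integrated absolute error
MIAE = ∫_B E|f^ − f| dλ, estimated by midpoint quadrature within each
Monte-Carlo replication. Discontinuities of f inflate pointwise errors only
on their (measure-zero) neighbourhoods, so MIAE still decreases under
refinement even for the discontinuous benchmark surface.

## Pseudopopulation bootstrap

The estimated map is promoted to a complete surrogate population — the
Voronoi field of the original sample in the continuous setting (an exact
nearest-original-point lookup, deliberately *not* the display grid, so no
second discretisation enters), the mapped densities or values in the finite
settings. M bootstrap samples are drawn from the surrogate with the original
design object reused verbatim (same tessellation, blocks, or frame
probabilities — never re-estimated quantities), each is NN-interpolated
reading values off the surrogate, and

    rmse*(p) = [ (1/M) Σ_m (f^*_m(p) − f^(p))² ]^(1/2).

Where the field is differentiable with nonzero gradient and the design
guarantees a sampled point within a fixed radius, E{rmse*} is at most three
times the true RMSE; empirically the ratio settles around 1.2–1.6. The
default M = 1000 is a convention, not a guarantee; a stabilisation check
(doubling M moves rmse* by O(M^(−1/2))) is part of the suite. In the 3P
workflow the surrogate carries the mapped values ŷ_j, replicates draw
Poisson samples with the original π_j, interpolate pseudo-residuals
ŷ_j − x_j and rebuild maps as x_j + ê*_j.

## Synthetic populations

Three benchmark surfaces on the unit square generate all synthetic
populations, each scaled to a maximum of exactly L = 10:

1. (C1/2)(sin²p1 + cos²p2 + p1) — smooth, trended (Lipschitz);
2. C2·sin(3p1)·sin²(3p2) — smooth oscillating bump with interior maximum at
   (π/6, π/6);
3. C3·p1·p2 where min(p1, p2) ≤ 1/2, else C3·(1 + p1)·p2 — discontinuous
   exactly on the internal edges of the upper-right quadrant.

The constants are not hard-coded: they are derived at first use by a dense
grid search refined by bounded local maximisation (C1 = 20/(sin²1 + 2) ≈
7.3853, C2 = 10, C3 = 5), so a corrected surface reading would propagate
automatically. Surface 3's maximiser sits on a discontinuity boundary, so
its constant comes from the grid corner directly.

Area populations integrate the surfaces over quadrats by the midpoint rule
on a 20×20 sub-grid per quadrat — exact for piecewise-constant fields,
second-order otherwise, and the discontinuities of surface 3 align with
quadrat edges for the even grid sizes used, so no quadrat straddles a jump.

Unit populations come in four nested patterns on the ladder 500/1000/1500
(each level a prefix of the next): *regular* (sequential uniform proposals
rejected within 0.5·N_level^(−1/2) of any accepted point, 10 000-rejection
cap), *random* (i.i.d. uniform), *trended* ((1 − u1², 1 − u2²), densest
toward the upper-right corner), and *clustered* (10 uniform centres, 50
points per cluster per level from a circular Gaussian with per-coordinate
variance 0.025, out-of-region points redrawn). For 3P sampling, units with
y < l = 4 are dropped, expert predictions follow x = a + b·y with
b = 1 − ρ(L + l)/(L − l), a = (1 + ρ)l − b·l and ρ = 0.10 (relative error
exactly ρ at both extremes of [l, L]), and π_j = x_j/50. The truncation
floors the probabilities at l/L* = 0.08 and the model yields an expected
sampling fraction near 12 % on all three surfaces.

What the generator does *not* emulate: measurement error (observations are
exact field evaluations), irregular region shapes, anisotropy, and spatially
correlated prediction errors in the 3P frame. Tests passing on these
populations therefore validate the design-based machinery — not robustness
to observation noise, which the theory does not cover.

## Monte-Carlo harness and problem sizes

Each configuration replicates the survey R times, accumulating per-point
error moments and mean bootstrap RMSE; reported indicators are |mean error|
(absolute bias — the alternative reading mean|error| would break the
testable identity RMSE² = bias² + variance), RMSE, and mean(rmse*)/RMSE,
summarised by min/avg/max over the support. Points with exactly zero
Monte-Carlo RMSE get an undefined-ratio marker and are excluded from ratio
summaries with an explicit count. Replication r of a configuration draws its
generator from (master seed, configuration hash, r), so any single cell of
the study is reproducible in isolation and replications are parallelisable.

Two presets exist: `paper` (R = 10 000, M = 1000, 100×100 continuous
evaluation grid, full size ladders — cluster-scale, and it warns so) and
`desk` (R = 500, M = 100, 25×25 evaluation grid, the two smallest sizes per
ladder), the package's own scaled-down design whose directional conclusions
(error decay under refinement, ratio ≥ 1 on average) match the full-scale
ones. The acceptance script uses R = 1000 × M = 200 at a single evaluation
point for the conservativeness ratio and N = 1500 populations for the 3P
sampling fraction.

## Numerical choices and limitations

- Tie tolerance 1e-9 absolute; region coordinates are planar Cartesian in
  user units, no CRS handling.
- The batched continuous bootstrap computes squared distances by the
  quadratic expansion (one matmul, no 4-D temporaries) and falls back to
  per-sample interpolation beyond ~2·10⁷ distance entries.
- SGS/SYS use one shared offset across all cells/blocks (aligned systematic
  design); blocks are 2 grid rows × 5 grid columns by convention.
- An empty 3P sample (possible since the size is random) is redrawn with a
  warning — an empty sample leaves the interpolator undefined.
- The regularity of unit patterns (every unit having many neighbours within
  t·N^(−1/2)) is existential in t: the suite verifies it at t = 8, where all
  stochastic patterns satisfy it with margin, and reports the regular
  pattern, whose inter-point spacing is bounded below by construction.
- Bound computations are empirical validations, not proofs: the suite checks
  domination of Monte-Carlo errors within 3 standard errors, never exact
  inequalities between estimated quantities.
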