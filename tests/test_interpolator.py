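"""NN interpolation: oracle equivalence, tie averaging, range preservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nnmap.interpolator import (
    idw_interpolate,
    nn_interpolate,
    nn_map_areas,
    nn_map_units,
    nn_values,
    residual_interpolate,
)
from nnmap.populations import UnitPopulation, make_area_population
from nnmap.sampling import SampleRealization, SchemeSpec, draw_srswor


def brute_force_nn(sxy, svals, qxy, tie_tol=1e-9):
    """Literal per-query scan: average all observations at minimal distance."""
    out = []
    for q in qxy:
        d = np.sqrt(((sxy - q) ** 2).sum(axis=1))
        out.append(svals[d <= d.min() + tie_tol].mean())
    return np.array(out)


class TestCoreRule:
    def test_single_point_gives_constant_map(self):
        s = SampleRealization(np.array([[0.3, 0.7]]), values=np.array([2.5]))
        est = nn_interpolate(s, np.random.default_rng(0).random((20, 2)))
        assert (est.values == 2.5).all()

    def test_exact_tie_averages(self):
        s = SampleRealization(np.array([[0.0, 0.0], [1.0, 1.0]]),
                              values=np.array([0.0, 8.0]))
        est = nn_interpolate(s, np.array([[0.5, 0.5]]))
        assert est.values[0] == pytest.approx(4.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 13)
        sxy = rng.random((n, 2))
        svals = rng.random(n) * 10
        qxy = rng.random((rng.integers(1, 51), 2))
        np.testing.assert_array_equal(
            nn_values(sxy, svals, qxy), brute_force_nn(sxy, svals, qxy)
        )

    def test_accelerated_path_matches_oracle(self):
        # force the tree-based branch (n above the brute-force cutoff)
        rng = np.random.default_rng(42)
        sxy = rng.random((300, 2))
        svals = rng.random(300) * 10
        qxy = rng.random((200, 2))
        np.testing.assert_allclose(
            nn_values(sxy, svals, qxy), brute_force_nn(sxy, svals, qxy), atol=1e-12
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            nn_values(np.empty((0, 2)), np.empty(0), np.array([[0.5, 0.5]]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_range_preservation_and_exactness(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        sxy = rng.random((n, 2))
        svals = rng.random(n) * 10
        qxy = rng.random((40, 2))
        vals = nn_values(sxy, svals, qxy)
        assert vals.min() >= svals.min() - 1e-12
        assert vals.max() <= svals.max() + 1e-12
        # interpolation error is zero at sampled locations
        np.testing.assert_allclose(nn_values(sxy, svals, sxy), svals, atol=1e-12)

    def test_dichotomous_support_preserved(self):
        rng = np.random.default_rng(3)
        sxy = rng.random((25, 2))
        svals = (rng.random(25) < 0.5).astype(float)
        vals = nn_values(sxy, svals, rng.random((300, 2)))
        assert set(np.unique(vals)) <= {0.0, 1.0}


class TestIdwLimit:
    @pytest.mark.parametrize("seed", range(20))
    def test_large_alpha_approaches_nn(self, seed):
        rng = np.random.default_rng(seed)
        sxy = rng.random((10, 2))
        svals = rng.random(10) * 10
        qxy = rng.random((200, 2))
        # the limit argument needs the nearest sample point to be an isolated
        # minimiser: keep queries whose second-nearest distance exceeds the
        # nearest by >15%, so (d1/d2)**200 is negligible
        d = np.sqrt(((qxy[:, None] - sxy[None, :]) ** 2).sum(-1))
        d.sort(axis=1)
        clear = d[:, 1] > 1.15 * d[:, 0]
        assert clear.sum() > 50
        qxy = qxy[clear]
        nn = nn_values(sxy, svals, qxy)
        idw = idw_interpolate(sxy, svals, qxy, alpha=200.0)
        assert np.abs(nn - idw).max() < 1e-6

    def test_single_sample_and_symmetry(self):
        assert idw_interpolate(np.array([[0.5, 0.5]]), np.array([3.0]),
                               np.array([[0.1, 0.1]]), alpha=2.0)[0] == 3.0
        # two equidistant points average for any alpha
        v = idw_interpolate(np.array([[0.0, 0.5], [1.0, 0.5]]), np.array([2.0, 6.0]),
                            np.array([[0.5, 0.5]]), alpha=2.0)
        assert v[0] == pytest.approx(4.0)

    def test_coincident_query_returns_observation(self):
        sxy = np.array([[0.25, 0.25], [0.75, 0.75]])
        v = idw_interpolate(sxy, np.array([1.0, 9.0]), sxy, alpha=2.0)
        np.testing.assert_allclose(v, [1.0, 9.0])


class TestFinitePopulationMaps:
    def test_sampled_areas_keep_their_density(self):
        pop = make_area_population(1, g=10)
        idx = draw_srswor(pop.N, 10, np.random.default_rng(0))
        sample = SampleRealization(pop.centroids[idx], values=pop.densities[idx],
                                  indices=idx, spec=SchemeSpec("srswor", n=10))
        est = nn_map_areas(sample, pop)
        np.testing.assert_allclose(est.values[idx], pop.densities[idx])

    def test_single_sampled_area_floods_the_grid(self):
        pop = make_area_population(2, g=10)
        idx = np.array([42])
        sample = SampleRealization(pop.centroids[idx], values=pop.densities[idx],
                                  indices=idx)
        est = nn_map_areas(sample, pop)
        assert (est.values == pop.densities[42]).all()

    def test_equidistant_quadrats_average(self):
        pop = make_area_population(1, g=4)
        # sample quadrats 0 and 2 in the bottom row; quadrat 1 sits midway
        idx = np.array([0, 2])
        sample = SampleRealization(pop.centroids[idx], values=pop.densities[idx],
                                  indices=idx)
        est = nn_map_areas(sample, pop)
        assert est.values[1] == pytest.approx(pop.densities[idx].mean())

    def test_unit_lattice_four_way_average(self):
        # units on a 3x3 lattice; centre node equidistant from 4 sampled nodes
        xs = np.linspace(0.25, 0.75, 3)
        gx, gy = np.meshgrid(xs, xs)
        locs = np.column_stack([gx.ravel(), gy.ravel()])
        pop = UnitPopulation(locs, values=np.arange(9.0))
        idx = np.array([1, 3, 5, 7])  # edge midpoints around the centre
        sample = SampleRealization(locs[idx], values=pop.values[idx], indices=idx)
        est = nn_map_units(sample, pop)
        assert est.values[4] == pytest.approx(pop.values[idx].mean())
        assert est.values.min() >= pop.values[idx].min()
        assert est.values.max() <= pop.values[idx].max()


class TestResidualInterpolation:
    def test_perfect_predictions_reproduce_the_frame(self, threep_population):
        pop = threep_population
        perfect = UnitPopulation(pop.locations, pop.values,
                                 predictions=pop.values, pi=pop.pi)
        idx = np.arange(0, perfect.N, 7)
        sample = SampleRealization(perfect.locations[idx], values=perfect.values[idx],
                                  indices=idx, predictions=perfect.predictions[idx])
        est = residual_interpolate(sample, perfect)
        np.testing.assert_allclose(est.values, perfect.values, atol=1e-12)

    def test_sampled_units_recover_their_value(self, threep_population):
        pop = threep_population
        idx = np.arange(0, pop.N, 11)
        sample = SampleRealization(pop.locations[idx], values=pop.values[idx],
                                  indices=idx, predictions=pop.predictions[idx])
        est = residual_interpolate(sample, pop)
        np.testing.assert_allclose(est.values[idx], pop.values[idx], atol=1e-12)

    def test_error_bounded_by_residual_spread(self, threep_population):
        pop = threep_population
        idx = np.arange(0, pop.N, 5)
        sample = SampleRealization(pop.locations[idx], values=pop.values[idx],
                                  indices=idx, predictions=pop.predictions[idx])
        est = residual_interpolate(sample, pop)
        e = pop.values - pop.predictions
        spread = e.max() - e.min()
        worst = np.abs(est.values - pop.values).max()
        assert worst <= np.abs(e[idx]).max() + spread + 1e-12

    def test_missing_predictions_rejected(self, threep_population):
        pop = threep_population
        bare = UnitPopulation(pop.locations, pop.values)
        idx = np.arange(10)
        sample = SampleRealization(pop.locations[idx], values=pop.values[idx],
                                  indices=idx, predictions=pop.predictions[idx])
        with pytest.raises(ValueError):
            residual_interpolate(sample, bare)
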