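"""Error bounds: oscillation, miss probabilities, rate and MIAE behaviour."""

import itertools
import math

import numpy as np
import pytest

from nnmap.bounds import (
    circle_rect_area,
    lipschitz_rate_bound,
    miae_mc,
    miss_prob_mc,
    miss_prob_pairwise_bound,
    miss_prob_tss,
    miss_prob_urs,
    oscillation,
    pointwise_error_bound,
)
from nnmap.interpolator import nn_values
from nnmap.populations import UNIT_SQUARE, surface_function
from nnmap.sampling import SchemeSpec, draw_locations_many

# a valid Lipschitz constant for surface 1 (gradient norm bound: the partial
# derivatives are bounded by C1 and C1/2, C1 = 20/(sin^2(1)+2) ~ 7.39)
SURFACE1_LIPSCHITZ = 8.5


def _grid_area_oracle(cx, cy, r, rect, res=1500):
    xs = np.linspace(rect[0], rect[2], res)
    ys = np.linspace(rect[1], rect[3], res)
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
    return inside.mean() * (rect[2] - rect[0]) * (rect[3] - rect[1])


class TestCircleRectArea:
    @pytest.mark.parametrize(
        "cx,cy,r,rect",
        [
            (0.5, 0.5, 0.1, (0, 0, 1, 1)),  # ball interior
            (0.0, 0.0, 0.3, (0, 0, 1, 1)),  # corner overlap
            (0.5, 0.0, 0.2, (0, 0, 1, 1)),  # edge overlap
            (0.5, 0.5, 2.0, (0, 0, 1, 1)),  # rectangle covered
            (0.9, 0.7, 0.35, (0.5, 0.5, 1.0, 1.0)),
            (1.5, 0.5, 0.2, (0, 0, 1, 1)),  # disjoint up to tangency
        ],
    )
    def test_against_grid_counting(self, cx, cy, r, rect):
        exact = circle_rect_area(cx, cy, r, *rect)
        approx = _grid_area_oracle(cx, cy, r, rect)
        assert exact == pytest.approx(approx, abs=5e-3)

    def test_interior_ball_is_exact(self):
        assert circle_rect_area(0.5, 0.5, 0.1, 0, 0, 1, 1) == pytest.approx(
            math.pi * 0.01, rel=1e-12
        )


class TestMissProbabilities:
    def test_urs_closed_forms(self):
        p = (0.5, 0.5)
        assert miss_prob_urs(UNIT_SQUARE, p, 0.1, 1).value == pytest.approx(
            1 - 0.01 * math.pi, rel=1e-12
        )
        assert miss_prob_urs(UNIT_SQUARE, p, 0.1, 2).value == pytest.approx(
            (1 - 0.01 * math.pi) ** 2, rel=1e-12
        )
        assert miss_prob_urs(UNIT_SQUARE, p, 1.5, 3).value == 0.0

    @pytest.mark.parametrize("p", [(0.5, 0.5), (0.05, 0.9), (1.0, 0.0)])
    @pytest.mark.parametrize("k", [2, 4])
    def test_tss_covering_radius_gives_zero(self, p, k):
        assert miss_prob_tss(UNIT_SQUARE, p, math.sqrt(2) / k, k).value == 0.0

    def test_tss_single_cell_equals_urs(self):
        p, delta = (0.3, 0.6), 0.15
        a = miss_prob_tss(UNIT_SQUARE, p, delta, 1).value
        b = miss_prob_urs(UNIT_SQUARE, p, delta, 1).value
        assert a == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize(
        "p,delta", list(itertools.product([(0.2, 0.2), (0.5, 0.8)], [0.05, 0.1, 0.25]))
    )
    @pytest.mark.parametrize("scheme", ["urs", "tss"])
    def test_analytic_matches_monte_carlo(self, scheme, p, delta):
        reps = 40_000
        if scheme == "urs":
            spec = SchemeSpec("urs", n=16)
            analytic = miss_prob_urs(UNIT_SQUARE, p, delta, 16)
        else:
            spec = SchemeSpec("tss", k=4)
            analytic = miss_prob_tss(UNIT_SQUARE, p, delta, 4)
        mc = miss_prob_mc(spec, UNIT_SQUARE, p, delta, reps, np.random.default_rng(8))
        se = max(mc.se, 1e-4)
        assert abs(mc.value - analytic.value) <= 3 * se

    def test_mc_zero_delta_misses_surely(self):
        mc = miss_prob_mc(SchemeSpec("urs", n=10), UNIT_SQUARE, (0.5, 0.5), 0.0,
                          1000, np.random.default_rng(0))
        assert mc.value == 1.0

    def test_sgs_never_misses_at_covering_radius(self):
        spec = SchemeSpec("sgs", k=5)
        mc = miss_prob_mc(spec, UNIT_SQUARE, (0.37, 0.81), math.sqrt(2) / 5,
                          2000, np.random.default_rng(1))
        assert mc.value == 0.0


class TestOscillation:
    def test_constant_field_has_zero_oscillation(self):
        const = lambda pts: np.full(len(np.atleast_2d(pts)), 3.0)
        assert oscillation(const, (0.5, 0.5), 0.2).value == 0.0

    @pytest.mark.parametrize("p,delta", [((0.5, 0.5), 0.1), ((0.2, 0.8), 0.05)])
    def test_lipschitz_field_bounded_by_beta_delta(self, p, delta):
        osc = oscillation(surface_function(1), p, delta)
        assert osc.value <= SURFACE1_LIPSCHITZ * delta

    def test_discontinuity_jump_detected(self):
        # just above the horizontal quadrant edge the field jumps by C3*p2
        osc = oscillation(surface_function(3), (0.5, 0.75), 1e-3, resolution=101)
        assert osc.value == pytest.approx(3.75, abs=0.05)

    def test_monotone_in_delta(self):
        f = surface_function(2)
        values = [oscillation(f, (0.4, 0.4), d).value for d in (0.05, 0.1, 0.2)]
        assert values == sorted(values)


def _mc_abs_error(surface_id, spec, p, reps, seed):
    f = surface_function(surface_id)
    p = np.asarray(p, dtype=float)
    locs = draw_locations_many(spec, UNIT_SQUARE, reps, np.random.default_rng(seed))
    errs = np.empty(reps)
    for r in range(reps):
        errs[r] = nn_values(locs[r], f(locs[r]), p[None, :])[0] - f(p[None, :])[0]
    return np.abs(errs)


class TestPointwiseBound:
    @pytest.mark.parametrize("sid", [1, 2, 3])
    @pytest.mark.parametrize(
        "spec", [SchemeSpec("urs", n=36), SchemeSpec("tss", k=6)]
    )
    @pytest.mark.parametrize("delta", [0.1, 0.2])
    def test_bound_dominates_mc_error(self, sid, spec, delta):
        p = (0.5, 0.5)
        bound = pointwise_error_bound(surface_function(sid), spec, UNIT_SQUARE, p, delta)
        abs_err = _mc_abs_error(sid, spec, p, reps=2000, seed=11)
        mc, se = abs_err.mean(), abs_err.std(ddof=1) / np.sqrt(len(abs_err))
        assert mc <= bound + 3 * se

    def test_beyond_diameter_reduces_to_oscillation(self):
        spec = SchemeSpec("tss", k=4)
        delta = 1.5  # exceeds the unit-square diameter
        bound = pointwise_error_bound(surface_function(1), spec, UNIT_SQUARE,
                                      (0.5, 0.5), delta)
        osc = oscillation(surface_function(1), (0.5, 0.5), delta).value
        assert bound == pytest.approx(osc)


class TestPairwiseBound:
    def test_independent_closed_form(self):
        q = np.full(4, 0.2)
        assert miss_prob_pairwise_bound(q) == pytest.approx(1.0 / (4 * 0.2))
        assert miss_prob_pairwise_bound(np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_vacuous_bracket_returns_inf(self):
        # strongly negatively-correlated hits: sum(q) + sup_ratio - 1 <= 0
        q = np.array([0.1, 0.1])
        joint = np.full((2, 2), 0.005)
        assert miss_prob_pairwise_bound(q, joint=joint) == math.inf

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 10])
    def test_dominates_exact_independent_probability(self, n):
        # exact Pr{no hit} under independence is prod(1 - q_i)
        for qs in itertools.product((0.1, 0.5, 0.9), repeat=min(n, 3)):
            q = np.resize(np.array(qs), n)
            exact = np.prod(1 - q)
            assert miss_prob_pairwise_bound(q) >= exact - 1e-12


class TestRates:
    def test_tss_rate_bound_has_no_miss_term(self):
        k = 5
        spec = SchemeSpec("tss", k=k)
        n = k * k
        t = math.sqrt(2)
        bound = lipschitz_rate_bound(SURFACE1_LIPSCHITZ, t, n, spec, UNIT_SQUARE,
                                     (0.5, 0.5))
        assert bound == pytest.approx(SURFACE1_LIPSCHITZ * t / math.sqrt(n))

    def test_zero_beta_leaves_miss_term(self):
        spec = SchemeSpec("urs", n=16)
        b = lipschitz_rate_bound(0.0, 0.5, 16, spec, UNIT_SQUARE, (0.5, 0.5))
        expected = 10.0 * miss_prob_urs(UNIT_SQUARE, (0.5, 0.5), 0.5 / 4.0, 16).value
        assert b == pytest.approx(expected)

    def test_rmse_rate_near_root_n(self):
        # log RMSE vs log n regression under TSS on the smooth surface
        ns, rmses = [], []
        for k in (4, 6, 8, 10):
            abs_err = _mc_abs_error(1, SchemeSpec("tss", k=k), (0.5, 0.5),
                                    reps=1500, seed=21)
            ns.append(k * k)
            rmses.append(np.sqrt((abs_err**2).mean()))
        slope = np.polyfit(np.log(ns), np.log(rmses), 1)[0]
        assert -0.75 <= slope <= -0.25


class TestMiae:
    def test_decreasing_with_tessellation_refinement(self):
        vals = [
            miae_mc(surface_function(1), SchemeSpec("tss", k=k), reps=120,
                    rng=np.random.default_rng(31), grid_res=40).value
            for k in (4, 8)
        ]
        assert vals[1] < vals[0]

    def test_estimate_has_standard_error(self):
        est = miae_mc(surface_function(2), SchemeSpec("urs", n=16), reps=30,
                      rng=np.random.default_rng(5), grid_res=25)
        assert est.value > 0 and est.se > 0 and est.reps == 30
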