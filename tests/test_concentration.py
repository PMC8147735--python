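"""Concentration-index estimators, Wagstaff normalization, curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concindex import concentration as cc
from concindex.errors import DegenerateIndexError, ValidationError
from concindex.ranking import RankedSample, weighted_fractional_rank

from conftest import make_sample


def random_sample(seed: int, n: int | None = None, ties: bool = True) -> RankedSample:
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(3, 501))
    wealth = rng.normal(size=n)
    if ties and n > 4:
        # coarsen a random half of the wealth values to force tie blocks
        idx = rng.choice(n, size=n // 2, replace=False)
        wealth[idx] = np.round(wealth[idx], 1)
    w = rng.uniform(0.1, 5.0, size=n)
    r = weighted_fractional_rank(wealth, w)
    h = rng.binomial(1, np.clip(0.3 + 0.3 * r, 0, 1)).astype(float)
    if h.sum() == 0:  # keep mu > 0
        h[int(rng.integers(n))] = 1.0
    return RankedSample(h=h, r=r, w=w)


class TestCiDirect:
    def test_perfectly_pro_rich_binary(self, toy_sample):
        assert cc.ci_direct(toy_sample) == pytest.approx(0.5, abs=1e-12)

    def test_constant_indicator_gives_zero(self):
        s = make_sample([1, 1, 1, 1])
        assert cc.ci_direct(s) == pytest.approx(0.0, abs=1e-12)

    def test_alternating_indicator_hand_value(self):
        s = make_sample([1, 0, 1, 0])
        assert cc.ci_direct(s) == pytest.approx(-0.25, abs=1e-12)

    def test_reversed_ordering_flips_sign(self):
        s = make_sample([1, 1, 0, 0])
        assert cc.ci_direct(s) == pytest.approx(-0.5, abs=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateIndexError):
            cc.ci_direct(make_sample([0, 0, 0]))

    def test_single_respondent_rejected(self):
        s = RankedSample(h=[1.0], r=[0.5], w=[1.0])
        with pytest.raises(DegenerateIndexError):
            cc.ci_direct(s)


class TestCiRegression:
    def test_slope_matches_direct_on_toy(self, toy_sample):
        est = cc.ci_regression(toy_sample)
        assert est.value == pytest.approx(0.5, abs=1e-10)
        assert est.se > 0 and not est.normalized

    def test_constant_indicator_slope_zero(self):
        est = cc.ci_regression(make_sample([1, 1, 1, 1]))
        assert est.value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_slope_equals_direct_on_random_instances(self, seed):
        s = random_sample(seed, n=200)
        assert cc.ci_regression(s).value == pytest.approx(
            cc.ci_direct(s), abs=1e-10
        )


class TestWagstaff:
    def test_binary_half_mean_doubles(self):
        assert cc.wagstaff_normalize(0.5, 0.5, (0, 1)) == pytest.approx(1.0)

    def test_zero_preserved(self):
        assert cc.wagstaff_normalize(0.0, 0.3, (0, 1)) == 0.0

    def test_general_bounds_closed_form(self):
        # CI·mu·(b-a)/((mu-a)(b-mu)) = 0.1·2·4/(2·2)
        assert cc.wagstaff_normalize(0.1, 2.0, (0, 4)) == pytest.approx(0.2)

    @pytest.mark.parametrize("mu", [0.0, 1.0])
    def test_mean_at_bound_rejected(self, mu):
        with pytest.raises(DegenerateIndexError):
            cc.wagstaff_normalize(0.1, mu, (0, 1))


class TestEstimate:
    def test_insignificant_small_z(self, toy_sample):
        # z = 0.05/0.04 = 1.25 < 1.96: replicate via a direct z computation
        est = cc.estimate(toy_sample, normalize=False)
        assert est.significant == (abs(est.value / est.se) > 1.959963984540054)

    def test_flags_on_strong_estimate(self):
        rng = np.random.default_rng(11)
        n = 4000
        wealth = rng.normal(size=n)
        r = weighted_fractional_rank(wealth, np.ones(n))
        h = (rng.random(n) < 0.1 + 0.6 * r).astype(float)
        est = cc.estimate(RankedSample(h=h, r=r, w=np.ones(n)))
        assert est.significant and est.relevant and est.pro_rich

    def test_pro_poor_sign(self):
        rng = np.random.default_rng(12)
        n = 4000
        wealth = rng.normal(size=n)
        r = weighted_fractional_rank(wealth, np.ones(n))
        h = (rng.random(n) < 0.7 - 0.4 * r).astype(float)
        est = cc.estimate(RankedSample(h=h, r=r, w=np.ones(n)))
        assert est.significant and not est.pro_rich and est.value < 0

    def test_normalization_scales_value_and_se_together(self, toy_sample):
        raw = cc.estimate(toy_sample, normalize=False)
        wag = cc.estimate(toy_sample, normalize=True)
        factor = wag.value / raw.value
        assert wag.se == pytest.approx(raw.se * factor)
        assert wag.significant == raw.significant

    def test_knowledge_scale_bounds_used(self):
        s = make_sample([0, 1, 3, 4], bounds=(0, 4))
        wag = cc.estimate(s, normalize=True)
        factor = cc.wagstaff_factor(s.mu, (0, 4))
        assert wag.value == pytest.approx(cc.ci_direct(s) * factor, rel=1e-9)


class TestScaleInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_ci_invariant_to_positive_scaling_of_h_and_w(self, seed):
        s = random_sample(seed, n=150)
        base = cc.ci_direct(s)
        scaled_h = RankedSample(h=3.7 * s.h, r=s.r, w=s.w, bounds=(0, 3.7))
        scaled_w = RankedSample(h=s.h, r=s.r, w=11.0 * s.w)
        assert cc.ci_direct(scaled_h) == pytest.approx(base, abs=1e-12)
        assert cc.ci_direct(scaled_w) == pytest.approx(base, abs=1e-12)

    def test_replication_equals_weight_doubling(self):
        wealth = np.array([1.0, 2.0, 3.0, 4.0])
        h = np.array([0.0, 1.0, 0.0, 1.0])
        w = np.ones(4)
        r_dup = weighted_fractional_rank(np.append(wealth, 2.0), np.append(w, 1.0))
        s_dup = RankedSample(h=np.append(h, 1.0), r=r_dup, w=np.append(w, 1.0))
        w_dbl = np.array([1.0, 2.0, 1.0, 1.0])
        r_dbl = weighted_fractional_rank(wealth, w_dbl)
        s_dbl = RankedSample(h=h, r=r_dbl, w=w_dbl)
        assert cc.ci_direct(s_dup) == pytest.approx(cc.ci_direct(s_dbl), abs=1e-12)


class TestConcentrationCurve:
    def test_constant_indicator_is_diagonal(self):
        pts = cc.concentration_curve_points(make_sample([1, 1, 1, 1]))
        np.testing.assert_allclose(pts[:, 0], pts[:, 1], atol=1e-12)

    def test_toy_curve_vertices(self, toy_sample):
        pts = cc.concentration_curve_points(toy_sample)
        expected = [(0, 0), (0.25, 0), (0.5, 0), (0.75, 0.5), (1, 1)]
        np.testing.assert_allclose(pts, expected, atol=1e-12)

    def test_single_respondent_segment(self):
        s = RankedSample(h=[1.0], r=[0.5], w=[2.0])
        pts = cc.concentration_curve_points(s)
        np.testing.assert_allclose(pts, [(0, 0), (1, 1)], atol=1e-12)

    def test_negative_h_rejected(self):
        s = RankedSample(h=[-1.0, 1.0], r=[0.25, 0.75], w=[1.0, 1.0],
                         bounds=(-2, 2))
        with pytest.raises(ValidationError):
            cc.concentration_curve_points(s)

    def test_grid_interpolation_hits_endpoints(self, toy_sample):
        pts = cc.concentration_curve_points(toy_sample, grid=10)
        assert pts.shape == (11, 2)
        assert pts[0, 1] == 0.0 and pts[-1, 1] == 1.0

    def test_monotone_nondecreasing(self):
        s = random_sample(3, n=100)
        pts = cc.concentration_curve_points(s)
        assert (np.diff(pts[:, 1]) >= -1e-12).all()


class TestCurveArea:
    def test_diagonal_gives_zero(self):
        pts = np.column_stack([np.linspace(0, 1, 5), np.linspace(0, 1, 5)])
        assert cc.ci_from_curve_area(pts) == pytest.approx(0.0, abs=1e-12)

    def test_toy_curve_area_matches_direct(self, toy_sample):
        pts = cc.concentration_curve_points(toy_sample)
        assert cc.ci_from_curve_area(pts) == pytest.approx(0.5, abs=1e-12)

    def test_curve_above_diagonal_is_negative(self):
        s = make_sample([1, 1, 0, 0])  # pro-poor: curve above diagonal
        pts = cc.concentration_curve_points(s)
        assert cc.ci_from_curve_area(pts) < 0

    def test_unsorted_points_rejected(self):
        with pytest.raises(ValidationError):
            cc.ci_from_curve_area(np.array([[0, 0], [0.8, 0.5], [0.4, 0.6], [1, 1]]))

    def test_area_agrees_with_direct_at_scale(self):
        s = random_sample(21, n=10_000, ties=False)
        pts = cc.concentration_curve_points(s)
        assert cc.ci_from_curve_area(pts) == pytest.approx(
            cc.ci_direct(s), abs=1e-3
        )
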