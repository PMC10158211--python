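"""Partial-R^2 adjustment: exactness for a real omitted regressor, robustness values."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qbalin.partial_r2 import (
    PartialR2Params,
    adjust,
    benchmark_partial_r2,
    bias_magnitude,
    contour_grid,
    extreme_confounder_bound,
    robustness_value,
)
from qbalin.regression import NaiveFit, fit_naive, partial_stats, summary_from_published
from qbalin.results import GridSpec
from qbalin.synthetic import generate, preset


def _confounded_dataset(seed):
    data, truth = generate(preset("strong_confounder"), seed=seed)
    return data, truth.u


def _sample_phi(data, u):
    """Sample partial R^2 values of a realized confounder."""
    r2_xu = float(
        partial_stats(data.x, np.column_stack([u, data.covariates]))["partial_r2"].iloc[0]
    )
    full = fit_naive(data.with_covariate("_u", u))
    r2_yu = float(full.covariates.loc["_u", "partial_r2_y"])
    return r2_xu, r2_yu, full


class TestBiasMagnitude:
    def test_zero_outcome_association_gives_zero_bias(self, bcg_fit):
        assert bias_magnitude(bcg_fit, PartialR2Params(0.1, 0.0)) == 0.0

    def test_scaling_in_r2_yu_is_square_root(self, bcg_fit):
        b1 = bias_magnitude(bcg_fit, PartialR2Params(0.1, 0.05))
        b2 = bias_magnitude(bcg_fit, PartialR2Params(0.1, 0.10))
        assert b2 == pytest.approx(math.sqrt(2) * b1, rel=1e-12)

    def test_fully_explanatory_confounder_rejected(self, bcg_fit):
        with pytest.raises(ValueError):
            PartialR2Params(1.0, 0.5)

    def test_matches_omitted_variable_gap_for_real_regressor(self):
        data, u = _confounded_dataset(3)
        naive = fit_naive(data)
        r2_xu, r2_yu, full = _sample_phi(data, u)
        gap = abs(naive.estimate - full.estimate)
        assert bias_magnitude(naive, PartialR2Params(r2_xu, r2_yu)) == pytest.approx(gap, abs=1e-8)


class TestAdjust:
    def test_null_confounder_preserves_estimate(self, bcg_fit):
        res = adjust(bcg_fit, PartialR2Params(0.0, 0.0))
        assert res.estimate == bcg_fit.estimate
        assert res.se == pytest.approx(
            bcg_fit.se * math.sqrt(bcg_fit.df / (bcg_fit.df - 1)), rel=1e-12
        )
        assert res.df == bcg_fit.df - 1

    def test_reproduces_fully_adjusted_regression(self):
        # the adjustment is an exact identity when fed a real U's sample partial R^2
        for seed in (1, 2):
            data, u = _confounded_dataset(seed)
            naive = fit_naive(data)
            r2_xu, r2_yu, full = _sample_phi(data, u)
            direction = "toward-null" if abs(full.estimate) < abs(naive.estimate) else "away-from-null"
            res = adjust(naive, PartialR2Params(r2_xu, r2_yu, direction))
            assert res.estimate == pytest.approx(full.estimate, abs=1e-8)
            assert res.se == pytest.approx(full.se, abs=1e-8)

    def test_se_monotone_in_both_parameters(self, bcg_fit):
        base = adjust(bcg_fit, PartialR2Params(0.1, 0.1)).se
        assert adjust(bcg_fit, PartialR2Params(0.1, 0.2)).se < base  # U explains noise
        assert adjust(bcg_fit, PartialR2Params(0.2, 0.1)).se > base  # U absorbs X variance

    def test_null_contour_point_drives_estimate_to_zero(self, bcg_fit):
        rv = robustness_value(bcg_fit, q=1.0)
        res = adjust(bcg_fit, PartialR2Params(rv, rv, "toward-null"))
        assert abs(res.estimate) < 1e-6


class TestRobustnessValue:
    def test_published_cohort_point_and_t_values(self, bcg_fit):
        assert robustness_value(bcg_fit, q=1.0) == pytest.approx(0.1876, abs=0.002)
        assert robustness_value(bcg_fit, q=1.0, alpha=0.05) == pytest.approx(0.1156, abs=0.002)

    def test_null_t_gives_zero(self):
        fit = summary_from_published(0.0, -1.0, 1.0, 0.95, 100, 3)
        assert robustness_value(fit, q=1.0) == 0.0

    @pytest.mark.parametrize("q", [0.3, 0.7, 1.0])
    def test_defining_property_removes_fraction_q(self, bcg_fit, q):
        rv = robustness_value(bcg_fit, q=q)
        res = adjust(bcg_fit, PartialR2Params(rv, rv, "toward-null"))
        assert res.estimate == pytest.approx((1 - q) * bcg_fit.estimate, abs=1e-6)

    @given(t=st.floats(0.1, 20), df=st.integers(10, 2000))
    def test_bounded_and_monotone_in_t(self, t, df):
        def fit_for(tv):
            se = 1.0
            return NaiveFit(estimate=tv * se, se=se, t_value=tv, df=df, n=df + 3, n_params=3)

        rv = robustness_value(fit_for(t), q=1.0)
        assert 0 <= rv < 1
        assert robustness_value(fit_for(t + 0.5), q=1.0) > rv

    def test_vanishes_as_q_shrinks(self, bcg_fit):
        assert robustness_value(bcg_fit, q=1e-9) < 1e-8


class TestExtremeConfounderBound:
    def test_null_t_gives_zero(self):
        fit = summary_from_published(0.0, -1.0, 1.0, 0.95, 100, 3)
        assert extreme_confounder_bound(fit) == 0.0

    @pytest.mark.parametrize("q", [0.5, 1.0])
    def test_bound_removes_exactly_fraction_q_at_worst_case(self, bcg_fit, q):
        r2x = extreme_confounder_bound(bcg_fit, q=q)
        bias = bias_magnitude(bcg_fit, PartialR2Params(r2x, 1.0))
        assert bias == pytest.approx(q * abs(bcg_fit.estimate), rel=1e-9)

    def test_matches_grid_search_and_sits_below_rv(self, bcg_fit):
        # independent 1-D root-finding oracle for the worst-case bound
        from scipy.optimize import brentq

        target = abs(bcg_fit.estimate)
        oracle = brentq(
            lambda r: bias_magnitude(bcg_fit, PartialR2Params(r, 1.0)) - target, 0, 0.999,
            xtol=1e-12,
        )
        bound = extreme_confounder_bound(bcg_fit, q=1.0)
        rv = robustness_value(bcg_fit, q=1.0)
        assert bound == pytest.approx(oracle, abs=1e-9)
        assert rv**2 <= bound <= rv  # worst-case r2_yu=1 needs less exposure-side strength


class TestBenchmarks:
    def test_unit_multiplier_equals_direct_partial_r2(self):
        data, _ = _confounded_dataset(5)
        fit = fit_naive(data)
        entries = {e.name: e for e in benchmark_partial_r2(data, fit)}
        for name, row in fit.covariates.iterrows():
            assert entries[name].values["r2_xu"] == pytest.approx(row["partial_r2_x"], abs=1e-12)
            assert entries[name].values["r2_yu"] == pytest.approx(row["partial_r2_y"], abs=1e-12)

    def test_independent_covariate_has_negligible_benchmark(self):
        rng = np.random.default_rng(0)
        n = 5000
        from qbalin.regression import Dataset

        noise = rng.standard_normal(n)
        x = (rng.random(n) < 0.4).astype(float)
        y = 1.0 * x + rng.standard_normal(n)
        data = Dataset(y=y, x=x, covariates=noise.reshape(-1, 1), covariate_names=("junk",))
        entry = benchmark_partial_r2(data)[0]
        assert entry.values["r2_xu"] < 0.01
        assert entry.values["r2_yu"] < 0.01

    def test_maternal_weight_analogue_ranks_first(self, bcg_like_data):
        data, _ = bcg_like_data
        entries = benchmark_partial_r2(data)
        assert entries[0].name == "mother_weight"

    def test_summary_only_fit_refused(self, bcg_fit):
        data, _ = _confounded_dataset(1)
        with pytest.raises(ValueError, match="requires data"):
            benchmark_partial_r2(data, bcg_fit)


class TestContours:
    def test_naive_level_set_runs_along_the_axes(self, bcg_fit):
        cs = contour_grid(bcg_fit, "estimate", GridSpec(resolution=41))
        naive_levels = cs.levels["naive"]
        for seg in naive_levels:
            assert np.all(np.min(seg, axis=1) == 0)
        assert any((seg == 0).all(axis=1).any() for seg in naive_levels)  # passes through (0,0)

    def test_null_level_set_points_give_null_adjusted_estimate(self, bcg_fit):
        cs = contour_grid(bcg_fit, "estimate", GridSpec(resolution=101))
        pts = np.vstack(cs.levels["null"])
        grid_tol = 3 * abs(bcg_fit.estimate) * (0.4 / 100)
        for r2x, r2y in pts[::7]:
            res = adjust(bcg_fit, PartialR2Params(r2x, r2y, "toward-null"))
            assert abs(res.estimate) < grid_tol

    def test_diagonal_null_crossing_equals_robustness_value(self, bcg_fit):
        cs = contour_grid(bcg_fit, "estimate", GridSpec(resolution=201))
        pts = np.vstack(cs.levels["null"])
        diag = pts[np.argmin(np.abs(pts[:, 0] - pts[:, 1]))]
        rv = robustness_value(bcg_fit, q=1.0)
        assert diag[0] == pytest.approx(rv, abs=0.4 / 200)
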