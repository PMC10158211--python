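"""Tipping-point solving, self-verification, and the comparative benchmark report."""

from dataclasses import replace

import numpy as np
import pytest

from qbalin.partial_r2 import robustness_value
from qbalin.regression import fit_naive, summary_from_published
from qbalin.simulation import SimulationParams
from qbalin.synthetic import generate, preset
from qbalin.tipping import (
    comparative_report,
    confounding_function_path,
    partial_r2_diagonal,
    simulation_diagonal,
    solve_tipping,
    threshold_diagonal,
)


class TestSolveTipping:
    def test_partial_r2_null_tipping_equals_the_robustness_value(self, bcg_fit):
        tp = solve_tipping(
            partial_r2_diagonal(bcg_fit, "null-estimate"), "null-estimate",
            (0.0, 0.999), method="partial_r2",
        )
        assert tp.value == pytest.approx(robustness_value(bcg_fit, q=1.0), abs=1e-6)
        assert tp.verified

    def test_significance_tipping_matches_the_alpha_adjusted_robustness_value(self, bcg_fit):
        tp = solve_tipping(
            partial_r2_diagonal(bcg_fit, "significance", alpha=0.05), "significance",
            (0.0, 0.999), method="partial_r2", alpha=0.05,
        )
        assert tp.value == pytest.approx(robustness_value(bcg_fit, q=1.0, alpha=0.05), abs=1e-6)

    def test_threshold_significance_tipping_at_the_equal_correlation_value(self, bcg_fit):
        from qbalin.threshold import impact_threshold

        tp = solve_tipping(
            threshold_diagonal(bcg_fit, "significance"), "significance",
            (0.0, 0.99), method="threshold", alpha=0.05,
        )
        _, eq = impact_threshold(bcg_fit, alpha=0.05)
        assert tp.value == pytest.approx(eq, abs=0.01)
        assert tp.verified

    def test_confounding_function_closed_form_agrees_with_bisection(self):
        data, _ = generate(preset("strong_confounder"), seed=23)
        path, alpha0 = confounding_function_path(data, "null-estimate")
        tp = solve_tipping(path, "null-estimate", (0.0, 5 * abs(alpha0)),
                           method="confounding_function", tolerance=1e-8)
        assert tp.value == pytest.approx(alpha0, abs=1e-6 * max(abs(alpha0), 1))
        assert tp.verified

    def test_criterion_already_met_returns_path_start(self):
        fit = summary_from_published(0.3, -0.6, 1.2, 0.95, 200, 2)  # insignificant
        tp = solve_tipping(
            partial_r2_diagonal(fit, "significance"), "significance", (0.0, 0.9),
            method="partial_r2",
        )
        assert tp.value == 0.0
        assert "path start" in tp.note

    def test_unreachable_criterion_reported(self, bcg_fit):
        with pytest.raises(ValueError, match="no tipping point"):
            solve_tipping(partial_r2_diagonal(bcg_fit, "null-estimate"), "null-estimate",
                          (0.0, 0.01))

    def test_stochastic_simulation_tipping_self_verifies(self):
        from qbalin.simulation import standardize_for_sensitivity

        data, _ = generate(preset("strong_confounder"), seed=29)
        std, _ = standardize_for_sensitivity(data)
        params = SimulationParams(zeta_y=0.0, zeta_x=0.0, iterations=20, burn_in=5,
                                  chains=2, seed=1)
        path = simulation_diagonal(std, params, "null-estimate", zeta_ratio=0.5)
        res0 = path(0.0)
        tp = solve_tipping(path, "null-estimate", (0.0, 2.5), method="simulation",
                           stochastic=True, n_grid=9, mc_se=0.15 * res0)
        assert tp.verified


@pytest.fixture(scope="module")
def matched_cohort():
    # a continuous confounder built to mirror the strongest covariate, so
    # the 1x benchmark rows should bracket the fully adjusted estimate
    spec = replace(
        preset("strong_confounder"),
        u_type="standard-normal", rho=0.0,
        delta=(0.5, 0.15, 0.1), gamma=(1.6, 0.4, 0.3),
        zeta_y=1.6, zeta_x=0.5,
    )
    return generate(spec, seed=37), spec


class TestComparativeReport:
    def test_zero_multiplier_reproduces_the_naive_estimates(self, strong_data):
        data, _ = strong_data
        rep = comparative_report(
            data, multipliers=(0.0, 1.0), seed=1,
            sim_params=SimulationParams(zeta_y=0, zeta_x=0, iterations=15, burn_in=5,
                                        chains=1, seed=1),
        )
        naive = rep.naive.estimate
        for (method, direction, mult), cell in rep.cells.items():
            if mult != 0.0 or "error" in cell:
                continue
            if cell.get("estimate") is not None:
                assert cell["estimate"] == pytest.approx(naive, abs=1e-10)
            else:
                assert cell["significant"] == rep.naive.significant

    def test_partial_r2_rows_symmetric_about_naive(self, strong_data):
        data, _ = strong_data
        rep = comparative_report(data, methods=("partial_r2",), multipliers=(0.5, 1.0, 2.0))
        naive = rep.naive.estimate
        for k in (0.5, 1.0, 2.0):
            toward = rep.cells[("partial_r2", "toward-null", k)]["estimate"]
            away = rep.cells[("partial_r2", "away-from-null", k)]["estimate"]
            assert (toward + away) / 2 == pytest.approx(naive, rel=1e-9)

    def test_scenario_grid_shape_and_threshold_verdicts(self, strong_data):
        data, _ = strong_data
        rep = comparative_report(
            data, multipliers=(0.5, 1.0, 2.0), seed=2,
            sim_params=SimulationParams(zeta_y=0, zeta_x=0, iterations=15, burn_in=5,
                                        chains=1, seed=2),
        )
        assert len(rep.cells) == 4 * 2 * 3  # methods x directions x multipliers
        for k in (0.5, 1.0, 2.0):
            for d in ("toward-null", "away-from-null"):
                cell = rep.cells[("threshold", d, k)]
                assert cell["verdict"] in ("excludes 0", "includes 0")
        md = rep.to_markdown()
        assert "| naive |" in md

    def test_unit_multiple_rows_bracket_the_fully_adjusted_estimate(self, matched_cohort):
        (data, truth), spec = matched_cohort
        rep = comparative_report(
            data, methods=("partial_r2", "simulation"), multipliers=(1.0,), seed=3, u=truth.u,
            sim_params=SimulationParams(zeta_y=0, zeta_x=0, iterations=30, burn_in=10,
                                        chains=3, seed=3),
        )
        full = rep.fully_adjusted.estimate
        for method in ("partial_r2", "simulation"):
            toward = rep.cells[(method, "toward-null", 1.0)]
            away = rep.cells[(method, "away-from-null", 1.0)]
            margin = 3 * rep.fully_adjusted.se
            assert toward["estimate"] - margin <= full <= away["estimate"] + margin

    def test_toward_null_estimates_decrease_with_benchmark_multiple(self, bcg_like_data):
        # qualitative ordering of the scenario table: stronger assumed
        # confounding moves the adjusted estimate further toward the null
        data, _ = bcg_like_data
        rep = comparative_report(
            data, methods=("partial_r2", "simulation"), multipliers=(0.5, 1.0, 2.0), seed=4,
            sim_params=SimulationParams(zeta_y=0, zeta_x=0, iterations=25, burn_in=5,
                                        chains=2, seed=4),
        )
        for method in ("partial_r2", "simulation"):
            ests = [rep.cells[(method, "toward-null", k)]["estimate"] for k in (0.5, 1.0, 2.0)]
            assert ests[0] > ests[1] > ests[2]

    def test_report_deterministic_given_seed(self, strong_data):
        data, _ = strong_data
        kwargs = dict(
            methods=("partial_r2", "simulation"), multipliers=(1.0,), seed=5,
            sim_params=SimulationParams(zeta_y=0, zeta_x=0, iterations=15, burn_in=5,
                                        chains=1, seed=5),
        )
        a = comparative_report(data, **kwargs).to_dict()
        b = comparative_report(data, **kwargs).to_dict()
        assert a == b

    def test_unknown_method_rejected(self, strong_data):
        data, _ = strong_data
        with pytest.raises(ValueError, match="unknown methods"):
            comparative_report(data, methods=("nope",))
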