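"""Cohort engine: occupancy recursion, outcome and cost accumulation."""

import math
from dataclasses import replace

import numpy as np
import pytest

from rrmm_cea.dosing import CycleCostSchedule
from rrmm_cea.engine import (
    accumulate_costs,
    accumulate_outcomes,
    discount_factors,
    run_arm,
    run_cohort,
)
from rrmm_cea.errors import EngineError
from rrmm_cea.params import ModelSettings
from rrmm_cea.transitions import BaselineHazards, build_arm_matrices

SETTINGS = ModelSettings()


def _matrices(n=120, r=(0.03, 0.015, 0.03), hr=(1.0, 1.0)):
    base = BaselineHazards(*r)
    return build_arm_matrices(
        base, hr[0], hr[1], replace(SETTINGS, horizon_cycles=n)
    )


class TestRunCohort:
    def test_identity_matrices_keep_initial_distribution(self):
        occ = run_cohort(np.broadcast_to(np.eye(3), (10, 3, 3)).copy())
        np.testing.assert_array_equal(occ, np.tile([1.0, 0.0, 0.0], (11, 1)))

    def test_certain_death_absorbs_in_one_cycle(self):
        m = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        occ = run_cohort(np.broadcast_to(m, (5, 3, 3)).copy())
        np.testing.assert_array_equal(occ[1:], np.tile([0.0, 0.0, 1.0], (5, 1)))

    def test_matches_repeated_matrix_power_oracle(self):
        matrices = _matrices(40)
        occ = run_cohort(matrices)
        for t in (1, 7, 23, 40):
            expected = np.array([1.0, 0.0, 0.0]) @ np.linalg.matrix_power(
                matrices[0], t
            )
            np.testing.assert_allclose(occ[t], expected, atol=1e-12)

    def test_conservation_and_death_monotonicity(self):
        occ = run_cohort(_matrices())
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(occ[:, 2]) >= -1e-12)

    def test_bad_initial_rejected(self):
        with pytest.raises(EngineError):
            run_cohort(_matrices(5), initial=(0.5, 0.2, 0.2))


class TestAccumulateOutcomes:
    def _full_pfs_occ(self, horizon=120):
        return np.tile([1.0, 0.0, 0.0], (horizon + 1, 1))

    def test_everyone_dead_gives_zero(self):
        occ = np.tile([0.0, 0.0, 1.0], (121, 1))
        occ[0] = [1.0, 0.0, 0.0]
        ly, qaly, *_ = accumulate_outcomes(
            occ, 0.73, 0.676, 0.0, 0.0, np.zeros(120, bool), SETTINGS
        )
        assert (ly, qaly) == (0.0, 0.0)

    def test_full_horizon_pfs_undiscounted_closed_form(self):
        settings = replace(SETTINGS, discount_outcome_annual=0.0)
        ly, qaly, *_ = accumulate_outcomes(
            self._full_pfs_occ(), 0.73, 0.676, 0.0, -0.049,
            np.zeros(120, bool), settings,
        )
        assert ly == pytest.approx(10.0)
        assert qaly == pytest.approx(7.3)

    def test_zero_rate_equals_undiscounted_for_both_bases(self):
        for basis in ("annual", "per_cycle"):
            settings = replace(
                SETTINGS, discount_outcome_annual=0.0, discount_basis=basis
            )
            _, qaly, *_ = accumulate_outcomes(
                self._full_pfs_occ(), 0.5, 0.4, 0.0, 0.0, np.zeros(120, bool), settings
            )
            assert qaly == pytest.approx(120 * 0.5 / 12)

    def test_ae_disutility_only_on_treatment(self):
        on = np.zeros(120, bool)
        on[:18] = True
        settings = replace(SETTINGS, discount_outcome_annual=0.0)
        _, qaly_ae, *_ = accumulate_outcomes(
            self._full_pfs_occ(), 0.73, 0.676, 0.5, -0.1, on, settings
        )
        _, qaly_no, *_ = accumulate_outcomes(
            self._full_pfs_occ(), 0.73, 0.676, 0.5, -0.1, np.zeros(120, bool), settings
        )
        assert qaly_no - qaly_ae == pytest.approx(18 * 0.5 * 0.1 / 12)


class TestAccumulateCosts:
    def _flat_costs(self, c):
        return CycleCostSchedule(
            arm="x",
            on_treatment_cost_by_cycle=(c,) * 120,
            post_treatment_pfs_cost_per_cycle=c,
            pd_cost_per_cycle=0.0,
            ae_event_cost=0.0,
        )

    def test_zero_alive_occupancy_costs_nothing(self):
        occ = np.tile([0.0, 0.0, 1.0], (121, 1))
        occ[0] = [1.0, 0.0, 0.0]
        total, _ = accumulate_costs(
            occ, self._flat_costs(100.0), 0.0, np.zeros(120, bool), SETTINGS
        )
        assert total == 0.0

    def test_flat_cost_no_discount_is_arithmetic(self):
        occ = np.tile([1.0, 0.0, 0.0], (121, 1))
        settings = replace(SETTINGS, discount_cost_annual=0.0)
        total, _ = accumulate_costs(
            occ, self._flat_costs(7.5), 0.0, np.zeros(120, bool), settings
        )
        assert total == pytest.approx(120 * 7.5)

    def test_flat_cost_matches_geometric_series_closed_form(self):
        occ = np.tile([1.0, 0.0, 0.0], (121, 1))
        settings = replace(SETTINGS, discount_basis="annual")
        total, _ = accumulate_costs(
            occ, self._flat_costs(1.0), 0.0, np.zeros(120, bool), settings
        )
        q = 1.072 ** (-1 / 12)
        assert total == pytest.approx(q * (1 - q**120) / (1 - q), rel=1e-12)

    def test_discount_factor_bases_disagree_in_magnitude(self):
        ann = discount_factors(0.03, 120, "annual")
        cyc = discount_factors(0.03, 120, "per_cycle")
        assert np.all(cyc <= ann)
        assert ann[0] == pytest.approx(1.03 ** (-1 / 12))
        assert cyc[0] == pytest.approx(1.03 ** (-1))


class TestRunArm:
    def test_unit_hazard_ratios_match_comparator_outcomes(self, config, model):
        values = config.params.means()
        values["hr_pfs_drd"] = 1.0
        values["hr_os_drd"] = 1.0
        drd = run_arm(
            config.arms["drd"], model.baseline, values, config.settings,
            config.cost_model, cost_scale=1.0,
        )
        krd = run_arm(
            config.arms["krd"], model.baseline, values, config.settings,
            config.cost_model, cost_scale=1.0,
        )
        # identical epidemiology; only the cost schedules differ
        assert drd.total_ly == pytest.approx(krd.total_ly, abs=1e-12)
        np.testing.assert_allclose(
            drd.trace.occupancy, krd.trace.occupancy, atol=1e-14
        )
        assert drd.total_cost != krd.total_cost

    def test_totals_equal_trace_sums(self, base_result):
        for arm in base_result.arms.values():
            assert arm.total_cost == pytest.approx(arm.trace.cost_by_cycle.sum())
            assert arm.total_qaly == pytest.approx(arm.trace.qaly_by_cycle.sum())
            assert arm.total_ly == pytest.approx(arm.trace.ly_by_cycle.sum())

    def test_shorter_horizon_never_increases_totals(self, config):
        from rrmm_cea.pipeline import build_model, evaluate

        short_cfg = replace(
            config, settings=replace(config.settings, horizon_cycles=60)
        )
        long_model = build_model(config)
        # keep the long model's calibration so only the horizon differs
        short_model = build_model(config)
        short_model.config = short_cfg
        long_res = evaluate(long_model)
        short_res = evaluate(short_model)
        for name in long_res.arms:
            assert short_res.arms[name].total_cost <= long_res.arms[name].total_cost
            assert short_res.arms[name].total_qaly <= long_res.arms[name].total_qaly
            assert short_res.arms[name].total_ly <= long_res.arms[name].total_ly

    def test_half_cycle_correction_averages_boundaries(self, config, model):
        values = config.params.means()
        hc_settings = replace(config.settings, half_cycle_correction=True)
        arm = config.arms["krd"]
        plain = run_arm(arm, model.baseline, values, config.settings, config.cost_model)
        hc = run_arm(arm, model.baseline, values, hc_settings, config.cost_model)
        # trapezoid credits the initial (fully alive) half-cycle: more LY
        assert hc.total_ly > plain.total_ly

    def test_trace_frame_layout(self, base_result):
        frame = base_result.arms["krd"].trace.to_frame()
        assert list(frame.columns) == [
            "cycle", "occ_pfs", "occ_pd", "occ_death", "disc_cost", "disc_qaly", "ly",
        ]
        assert len(frame) == 120
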