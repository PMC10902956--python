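"""Hazard/probability transforms, matrix construction and calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from rrmm_cea.engine import life_years_from_matrices, run_cohort
from rrmm_cea.errors import CalibrationError, EngineError, ValidationError
from rrmm_cea.params import ModelSettings
from rrmm_cea.transitions import (
    BaselineHazards,
    apply_hazard_ratio,
    build_arm_matrices,
    calibrate_baseline,
    calibrate_cost_scale,
    matrix_from_hazards,
    prob_to_rate,
    rate_to_prob,
)

SETTINGS = ModelSettings()


class TestRateProb:
    def test_null_hazard(self):
        assert rate_to_prob(0.0) == 0.0

    def test_large_hazard_saturates(self):
        assert rate_to_prob(1e6) == pytest.approx(1.0)

    def test_closed_form(self):
        assert rate_to_prob(0.1, 1.0) == pytest.approx(1 - math.exp(-0.1), abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            rate_to_prob(-0.1)

    @given(rate=st.floats(0.0, 5.0), dt=st.floats(0.1, 2.0))
    @hyp_settings(derandomize=True, max_examples=200, deadline=None)
    def test_round_trip(self, rate, dt):
        assert prob_to_rate(rate_to_prob(rate, dt), dt) == pytest.approx(
            rate, abs=1e-9, rel=1e-9
        )


class TestApplyHazardRatio:
    def test_identity_and_null(self):
        assert apply_hazard_ratio(0.2, 1.0) == pytest.approx(0.2)
        assert apply_hazard_ratio(0.0, 3.7) == 0.0

    def test_closed_form(self):
        assert apply_hazard_ratio(0.1, 0.6) == pytest.approx(1 - 0.9**0.6)

    def test_degenerate_probability_rejected(self):
        with pytest.raises(ValidationError):
            apply_hazard_ratio(1.0, 0.5)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValidationError):
            apply_hazard_ratio(0.2, 0.0)

    @given(p=st.floats(0.0, 0.99), hr=st.floats(0.01, 5.0))
    @hyp_settings(derandomize=True, max_examples=200, deadline=None)
    def test_equals_hazard_scale_multiplication(self, p, hr):
        # 1 - (1-p)^hr must equal converting to a rate, scaling, converting back
        expected = rate_to_prob(hr * prob_to_rate(p)) if p > 0 else 0.0
        assert apply_hazard_ratio(p, hr) == pytest.approx(expected, abs=1e-12)


class TestMatrices:
    def test_invariants(self):
        m = matrix_from_hazards(0.06, 0.01, 0.04)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m[1, 0] == 0.0
        np.testing.assert_array_equal(m[2], [0.0, 0.0, 1.0])
        assert np.all((m >= 0) & (m <= 1))

    def test_zero_hazards_give_identity(self):
        np.testing.assert_allclose(matrix_from_hazards(0, 0, 0), np.eye(3))

    def test_os_hazard_ratio_transforms_pfs_death_probability(self):
        base = BaselineHazards(0.06, 0.01, 0.04)
        matrices = build_arm_matrices(base, 1.0, 0.46, SETTINGS)
        expected = 1 - (1 - rate_to_prob(0.01, 1.0)) ** 0.46
        assert matrices[0][0, 2] == pytest.approx(expected, abs=1e-14)

    def test_unit_hazard_ratios_reproduce_baseline(self):
        base = BaselineHazards(0.03, 0.015, 0.03)
        krd = build_arm_matrices(base, 1.0, 1.0, SETTINGS)
        drd = build_arm_matrices(base, 1.0, 1.0, SETTINGS)
        np.testing.assert_array_equal(krd, drd)

    def test_hr_pfs_includes_pfs_death_switch(self):
        base = BaselineHazards(0.03, 0.015, 0.03)
        m = build_arm_matrices(
            base, 0.6, 0.46, SETTINGS, hr_pfs_includes_pfs_death=True
        )[0]
        assert m[0, 2] == pytest.approx(rate_to_prob(0.015 * 0.6))
        assert m[1, 2] == pytest.approx(rate_to_prob(0.03 * 0.46))

    def test_time_homogeneous_over_horizon(self):
        base = BaselineHazards(0.03, 0.015, 0.03)
        matrices = build_arm_matrices(base, 0.6, 0.46, SETTINGS)
        assert matrices.shape == (120, 3, 3)
        np.testing.assert_array_equal(matrices[0], matrices[-1])


class TestCalibration:
    def test_recovers_known_mortality_scale(self):
        # synthetic truth: generate life-years from known hazards, re-calibrate
        truth = BaselineHazards(
            r_progress=math.log(2) / 26.0, r_die_pfs=0.02, r_die_pd=0.04
        )
        ly_truth = life_years_from_matrices(
            build_arm_matrices(truth, 1.0, 1.0, SETTINGS), SETTINGS
        )
        recovered = calibrate_baseline(ly_truth, SETTINGS)
        assert recovered.r_die_pfs == pytest.approx(0.02, rel=1e-4)
        assert recovered.r_die_pd == pytest.approx(0.04, rel=1e-4)

    def test_hits_published_comparator_life_years(self):
        hazards = calibrate_baseline(3.52, SETTINGS)
        achieved = life_years_from_matrices(
            build_arm_matrices(hazards, 1.0, 1.0, SETTINGS), SETTINGS
        )
        assert achieved == pytest.approx(3.52, abs=1e-6)

    def test_idempotent(self):
        first = calibrate_baseline(3.52, SETTINGS)
        achieved = life_years_from_matrices(
            build_arm_matrices(first, 1.0, 1.0, SETTINGS), SETTINGS
        )
        second = calibrate_baseline(achieved, SETTINGS)
        assert second.r_die_pfs == pytest.approx(first.r_die_pfs, rel=1e-6)

    def test_worse_survival_hr_never_gains_life_years(self, model):
        ly = []
        for hr_os in (0.3, 0.46, 0.7, 1.0, 1.5):
            matrices = build_arm_matrices(model.baseline, 0.6, hr_os, SETTINGS)
            ly.append(life_years_from_matrices(matrices, SETTINGS))
        assert all(a >= b - 1e-12 for a, b in zip(ly, ly[1:]))

    def test_life_years_match_closed_form_survival_sum(self, model):
        # independent oracle: closed-form occupancy of the discrete chain
        b = model.baseline
        a = math.exp(-(b.r_progress + b.r_die_pfs))  # stay in PFS
        p_prog = math.exp(-b.r_die_pfs) - a
        surv_pd = math.exp(-b.r_die_pd)
        t = np.arange(1, 121)
        pfs = a**t
        # PD(t) = sum_{s<=t} PFS(s-1) * p_prog * surv_pd^(t-s)
        pd_occ = np.array(
            [
                sum(a ** (s - 1) * p_prog * surv_pd ** (tt - s) for s in range(1, tt + 1))
                for tt in t
            ]
        )
        ly_closed = float((pfs + pd_occ).sum() / 12.0)
        matrices = build_arm_matrices(b, 1.0, 1.0, SETTINGS)
        assert life_years_from_matrices(matrices, SETTINGS) == pytest.approx(
            ly_closed, abs=1e-9
        )

    def test_unreachable_target_reports_bracket(self):
        with pytest.raises(CalibrationError, match="target"):
            calibrate_baseline(10.0, SETTINGS)  # equals full horizon: impossible
        with pytest.raises(CalibrationError):
            calibrate_baseline(0.0, SETTINGS)

    def test_cost_scale_is_exact_ratio(self):
        assert calibrate_cost_scale(5000.0, 15106.0) == pytest.approx(15106.0 / 5000.0)
        with pytest.raises(CalibrationError):
            calibrate_cost_scale(0.0, 100.0)


class TestMatrixValidation:
    def test_recovery_rejected(self):
        from rrmm_cea.transitions import validate_matrix

        bad = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0, 0, 1.0]])
        with pytest.raises(EngineError, match="recovery"):
            validate_matrix(bad)

    def test_nonstochastic_row_rejected(self):
        from rrmm_cea.transitions import validate_matrix

        bad = np.array([[0.9, 0.05, 0.1], [0.0, 0.9, 0.1], [0, 0, 1.0]])
        with pytest.raises(EngineError, match="sum to 1"):
            validate_matrix(bad)
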