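"""Process families: calibration closed forms, marginal-function identities."""

import numpy as np
import pytest
from scipy import integrate, optimize

from cifmiss.process import (
    CIFProcess,
    IntensityProcess,
    calibrate_cif_process,
    calibrate_intensity_process,
    evaluate_process,
    process_from_yaml,
    process_to_yaml,
)

TGRID = np.linspace(1e-6, 1.0, 41)


class TestIntensityCalibration:
    def test_matches_independent_numeric_solve(self):
        # independent oracle: solve the two constraints numerically
        def constraints(lams):
            l1, l2 = lams
            return [
                -np.expm1(-(l1 + l2)) - 0.6,          # P(T <= 1 | X=0) = 0.6
                l1 / (l1 + l2) - 0.6,                 # conditional type-1 share
            ]

        sol = optimize.fsolve(constraints, [0.5, 0.4], full_output=False)
        proc = calibrate_intensity_process(0.6, 0.6, tau=1.0)
        assert proc.lambda1 == pytest.approx(sol[0], abs=1e-9)
        assert proc.lambda2 == pytest.approx(sol[1], abs=1e-9)
        assert proc.lambda1 == pytest.approx(0.549774, abs=1e-6)
        assert proc.lambda2 == pytest.approx(0.366516, abs=1e-6)

    def test_control_arm_cif_at_tau(self):
        proc = calibrate_intensity_process(0.6, 0.6, tau=1.0)
        assert float(proc.F1(1.0, 0)) == pytest.approx(0.36, abs=1e-12)
        assert float(proc.F2(1.0, 0)) == pytest.approx(0.24, abs=1e-12)
        assert float(proc.S(1.0, 0)) == pytest.approx(0.4, abs=1e-12)

    def test_degenerate_no_competing_events(self):
        proc = calibrate_intensity_process(0.6, 1.0, tau=1.0)
        assert proc.lambda2 == 0.0

    @pytest.mark.parametrize("p_exit,p_type1", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.5)])
    def test_out_of_range_probabilities_raise(self, p_exit, p_type1):
        with pytest.raises(ValueError):
            calibrate_intensity_process(p_exit, p_type1)

    def test_closed_form_cif_equals_quadrature(self):
        proc = calibrate_intensity_process(0.6, 0.6, 0.75, 1.2, tau=1.0)
        for x in (0, 1):
            for t in (0.25, 0.7, 1.0):
                val, _ = integrate.quad(
                    lambda u: proc.S(u, x) * proc.lam1(u, x), 0, t, epsabs=1e-12
                )
                assert float(proc.F1(t, x)) == pytest.approx(val, abs=1e-8)


class TestCIFCalibration:
    def test_q_closed_form(self):
        proc = calibrate_cif_process(0.36, family="extended", tau=1.0)
        assert proc.q == pytest.approx(0.36 / -np.expm1(-1.0), abs=1e-9)
        assert proc.q == pytest.approx(0.569511, abs=1e-6)
        assert float(proc.F1(1.0, 0)) == pytest.approx(0.36, abs=1e-12)

    @pytest.mark.parametrize("family", ["indirect", "extended"])
    def test_competing_cif_at_tau(self, family):
        proc = calibrate_cif_process(0.36, family=family, tau=1.0)
        assert round(float(proc.F2(1.0, 0)), 2) == 0.27

    @pytest.mark.parametrize("f1", [(0.24, 0.39), (0.36, 0.27), (0.48, 0.15)])
    def test_all_design_rates(self, f1):
        target, f2 = f1
        proc = calibrate_cif_process(target, family="extended")
        assert round(float(proc.F2(1.0, 0)), 2) == f2

    def test_null_process_equal_arms(self):
        proc = calibrate_cif_process(0.36, exp_b=1.0, exp_b2=1.0, family="extended")
        assert np.allclose(proc.F1(TGRID, 1), proc.F1(TGRID, 0))
        assert np.allclose(proc.F2(TGRID, 1), proc.F2(TGRID, 0))

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError):
            calibrate_cif_process(0.95, family="extended", tau=1.0)

    def test_beta_zero_extended_equal_f1_but_not_f2(self):
        proc = calibrate_cif_process(0.36, exp_b=1.0, exp_b2=0.8, family="extended")
        assert np.allclose(proc.F1(TGRID, 1), proc.F1(TGRID, 0), atol=1e-14)
        assert np.max(np.abs(proc.F2(TGRID, 1) - proc.F2(TGRID, 0))) > 0.01


class TestEvaluateProcess:
    @pytest.mark.parametrize(
        "proc",
        [
            calibrate_intensity_process(0.6, 0.6, 0.75, 0.5),
            calibrate_cif_process(0.36, exp_b=0.8, family="indirect"),
            calibrate_cif_process(0.36, exp_b=0.8, exp_b2=1.2, family="extended"),
        ],
        ids=["intensity", "indirect", "extended"],
    )
    def test_identities(self, proc):
        for x in (0, 1):
            pt = evaluate_process(proc, TGRID, x)
            assert np.allclose(pt.S + pt.F1 + pt.F2, 1.0, atol=1e-12)
            assert np.allclose(pt.lam1, pt.f1 / pt.S, atol=1e-10)
            assert np.all(np.diff(pt.F1) >= -1e-12)
            assert np.all(np.diff(pt.F2) >= -1e-12)
            assert np.all(pt.f1 >= 0) and np.all(pt.f2 >= 0)
        assert float(evaluate_process(proc, 0.0, 0).S) == pytest.approx(1.0)

    def test_negative_time_raises(self):
        with pytest.raises(ValueError):
            evaluate_process(calibrate_intensity_process(0.6, 0.6), -0.1, 0)

    def test_intensity_cifs_sum_to_one_at_infinity(self):
        proc = calibrate_intensity_process(0.6, 0.6, 0.8, 1.3)
        t_big = 50.0 / proc.total_rate(0)
        pt = evaluate_process(proc, t_big, 0)
        assert float(pt.F1 + pt.F2) == pytest.approx(1.0, abs=1e-12)

    def test_cif_intensities_match_finite_differences(self):
        proc = calibrate_cif_process(0.36, exp_b=0.8, exp_b2=1.2, family="extended")
        h = 1e-6
        for x in (0, 1):
            for t in (0.2, 0.5, 0.9):
                num_f1 = (proc.F1(t + h, x) - proc.F1(t - h, x)) / (2 * h)
                num_f2 = (proc.F2(t + h, x) - proc.F2(t - h, x)) / (2 * h)
                S = float(proc.S(t, x))
                assert float(proc.lam1(t, x)) == pytest.approx(num_f1 / S, rel=1e-6)
                assert float(proc.lam2(t, x)) == pytest.approx(num_f2 / S, rel=1e-6)

    def test_undefined_intensity_when_no_survivors(self):
        proc = IntensityProcess(lambda1=5.0, lambda2=5.0, tau=1.0)
        pt = evaluate_process(proc, 200.0, 0)
        assert np.isnan(pt.lam1)  # S = 0: flagged, not a crash

    def test_custom_time_transform_subdensity_fallback(self):
        proc = CIFProcess(family="extended", q=0.5, beta=0.0, psi1=lambda t: t**2)
        h = 1e-6
        num = (proc.F1(0.5 + h, 0) - proc.F1(0.5 - h, 0)) / (2 * h)
        assert float(proc.f1(0.5, 0)) == pytest.approx(num, rel=1e-4)


def test_yaml_round_trip():
    for proc in (
        calibrate_intensity_process(0.6, 0.4, 0.75, 1.1),
        calibrate_cif_process(0.24, exp_b=0.9, exp_b2=0.8, family="extended"),
    ):
        clone = process_from_yaml(process_to_yaml(proc))
        assert type(clone) is type(proc)
        assert np.allclose(clone.F1(TGRID, 1), proc.F1(TGRID, 1))
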