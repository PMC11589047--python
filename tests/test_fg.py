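"""Fine-Gray fitting: Cox equivalence, consistency, variances, GOF."""

import subprocess

import numpy as np
import pytest
from scipy import optimize

from cifmiss.fg import (
    FGDivergedError,
    FineGrayRegression,
    fg_fit,
    fg_robust_variance,
    fg_timevarying_fit,
)
from cifmiss.ipcw import km_censoring
from cifmiss.process import calibrate_intensity_process
from cifmiss.simulate import ObservedDataset, simulate_observed

from conftest import PI_R, TAU


def _cox_loglik(gamma, time, event, x):
    """Explicit Cox log partial likelihood (Breslow), brute-force oracle."""
    ll = 0.0
    for i in np.flatnonzero(event):
        at_risk = time >= time[i]
        ll += gamma * x[i] - np.log(np.sum(np.exp(gamma * x[at_risk])))
    return ll


class TestCoxEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_fg_equals_cox_without_competing_events_or_censoring(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.integers(0, 2, n)
        time = rng.exponential(1.0, n) * np.exp(-0.4 * x)
        data = ObservedDataset(time=time, status=np.ones(n, dtype=int), x=x,
                               tau=float(time.max()))
        fit = fg_fit(data, weight_style="standard")
        event = np.ones(n, dtype=bool)
        res = optimize.minimize_scalar(
            lambda g_: -_cox_loglik(g_, time, event, x), bounds=(-4, 4), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta_ == pytest.approx(res.x, abs=1e-7)


def _mirror_data():
    times = np.array([0.1, 0.3, 0.5, 0.6, 0.8, 0.9])
    status = np.array([1, 2, 1, 0, 1, 2])
    t = np.concatenate([times, times])
    s = np.concatenate([status, status])
    x = np.repeat([0, 1], len(times))
    return ObservedDataset(time=t, status=s, x=x, tau=1.0)


def test_mirror_symmetric_arms_give_zero():
    fit = fg_fit(_mirror_data())
    assert fit.beta_ == pytest.approx(0.0, abs=1e-10)


def test_consistency_under_correct_specification(cif_indirect_08):
    data = simulate_observed(20_000, cif_indirect_08, pi_r=PI_R, rng_seed=71)
    fit = fg_fit(data)
    assert abs(fit.beta_ - np.log(0.8)) < 3 * fit.se_robust_[0]


def test_stabilized_and_standard_agree_at_large_n(cif_indirect_08):
    data = simulate_observed(50_000, cif_indirect_08, pi_r=PI_R, rng_seed=72)
    b_std = fg_fit(data, weight_style="standard").beta_
    b_stab = fg_fit(data, weight_style="stabilized").beta_
    assert abs(b_std - b_stab) < 0.01


def test_breslow_baseline_one_arm_closed_form():
    """No censoring, one arm: dGamma(t) = dN1(t) / #(FG at-risk at t)."""
    data = ObservedDataset(
        time=np.array([0.2, 0.4, 0.5, 0.7, 0.9]),
        status=np.array([1, 2, 1, 1, 0]),
        x=np.zeros(5, dtype=int),
        tau=1.0,
    )
    fit = FineGrayRegression(variance="none").fit(data)
    # FG risk sets: at 0.2 all 5; at 0.5 subjects {0.5,0.7,0.9} plus prior
    # type-2 at 0.4 -> 4; at 0.7 subjects {0.7,0.9} plus 0.4 -> 3
    expected = np.cumsum([1 / 5, 1 / 4, 1 / 3])
    assert np.allclose(fit.baseline_cumhaz_, expected, atol=1e-12)


def test_matches_reference_implementation(tmp_path):
    """crr() from R cmprsk as the independent oracle on one dataset."""
    proc = calibrate_intensity_process(0.6, 0.6, 0.75, 0.8, tau=TAU)
    data = simulate_observed(1500, proc, pi_r=PI_R, rng_seed=42)
    fit = fg_fit(data)
    csv = tmp_path / "d.csv"
    data.to_csv(csv)
    script = (
        'suppressMessages(library(cmprsk));'
        f'd <- read.csv("{csv}");'
        "f <- crr(d$time, d$status, cov1=d$x, failcode=1, cencode=0);"
        'cat(f$coef, sqrt(f$var[1,1]), sep="\\n")'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    beta_r, se_r = map(float, out.stdout.strip().split())
    assert fit.beta_ == pytest.approx(beta_r, abs=1e-6)
    assert fit.se_robust_[0] == pytest.approx(se_r, rel=5e-3)


class TestRobustVariance:
    def test_sandwich_close_to_bootstrap(self, cif_indirect_08):
        data = simulate_observed(2000, cif_indirect_08, pi_r=PI_R, rng_seed=11)
        fit = fg_fit(data)
        boot = fg_robust_variance(fit, data, method="bootstrap", n_boot=400, rng_seed=1)
        assert fit.se_robust_[0] == pytest.approx(boot[0], rel=0.10)

    def test_no_censoring_psi_vanishes(self, cif_indirect_08):
        """Without random withdrawal the censoring term of the sandwich is zero."""
        from cifmiss.fg import _build_engine, _censoring_psi, _score_info

        # administrative censoring only: all subjects with T > tau get status 0
        # at exactly tau, which the censoring KM treats as its only event time;
        # no weight ever evaluates Ghat there, and psi must vanish for the
        # subset observed before tau
        data = simulate_observed(3000, cif_indirect_08, pi_r=0.0, rng_seed=12)
        fit = fg_fit(data)
        ghat = km_censoring(data)
        eng = _build_engine(data.time, data.status, data.x, ghat, TAU, "stabilized", None)
        _, _, s0, xbar, _ = _score_info(eng, fit.coef_)
        psi = _censoring_psi(
            eng, fit.coef_, data.time, data.status, data.x, ghat,
            eng.w_event / s0, xbar,
        )
        assert np.max(np.abs(psi)) < 1e-10
        assert fit.se_robust_[0] == pytest.approx(fit.se_naive_[0], rel=0.2)

    def test_coverage_nominal(self, coverage_study):
        assert 0.93 <= coverage_study["fg_coverage"] <= 0.97


class TestTimeVarying:
    def test_reduces_to_constant_fit(self, cif_indirect_08):
        data = simulate_observed(2000, cif_indirect_08, pi_r=PI_R, rng_seed=13)
        tv = fg_timevarying_fit(data, b_form="t")
        const = fg_fit(data)
        # nu absorbs some effect, but a refit with b(t) = 0-like constant must
        # error out as collinear rather than silently succeed
        assert tv.coef_.shape == (2,)
        assert abs(tv.coef_[0] + tv.coef_[1] * 0.5 - const.beta_) < 0.2
        with pytest.raises(FGDivergedError):
            fg_timevarying_fit(data, b_form=lambda t: np.ones_like(t))

    def test_logt_supported(self, cif_indirect_08):
        data = simulate_observed(2000, cif_indirect_08, pi_r=PI_R, rng_seed=14)
        tv = fg_timevarying_fit(data, b_form="logt")
        assert np.isfinite(tv.wald_nu_) and 0 <= tv.p_value_nu_ <= 1

    def test_size_under_constant_effect(self, coverage_study):
        """Wald test of nu = 0 holds its level when the true effect is constant."""
        rate = coverage_study["tv_rejection"]
        se = np.sqrt(0.05 * 0.95 / coverage_study["n_rep"])
        assert abs(rate - 0.05) < 4 * se


class TestAPI:
    def test_sklearn_params_round_trip(self):
        est = FineGrayRegression(weight_style="standard", max_iter=10)
        params = est.get_params()
        clone = FineGrayRegression().set_params(**params)
        assert clone.get_params() == params
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)

    def test_fit_with_arrays(self, cif_indirect_08):
        data = simulate_observed(800, cif_indirect_08, pi_r=PI_R, rng_seed=15)
        y = np.rec.fromarrays([data.status, data.time], names=["status", "time"])
        fit = FineGrayRegression().fit(data.x.reshape(-1, 1), y, tau=TAU)
        ref = fg_fit(data)
        assert fit.beta_ == pytest.approx(ref.beta_, abs=1e-12)

    def test_predict_cif_monotone(self, cif_indirect_08):
        data = simulate_observed(2000, cif_indirect_08, pi_r=PI_R, rng_seed=16)
        fit = fg_fit(data)
        ts = np.linspace(0, 1, 21)
        for x in (0, 1):
            curve = fit.predict_cif(x, ts)
            assert np.all(np.diff(curve) >= 0)
            assert np.all((curve >= 0) & (curve <= 1))

    def test_diverges_without_events_in_one_arm(self):
        rng = np.random.default_rng(5)
        n = 200
        x = np.repeat([0, 1], n // 2)
        time = rng.uniform(0.05, 1.0, n)
        status = np.where(x == 0, 1, 0)
        data = ObservedDataset(time=time, status=status, x=x, tau=1.0)
        with pytest.raises(FGDivergedError):
            fg_fit(data)

    def test_no_events_raises(self):
        data = ObservedDataset(
            time=np.array([0.5, 0.6]), status=np.array([0, 2]),
            x=np.array([0, 1]), tau=1.0,
        )
        with pytest.raises(ValueError):
            fg_fit(data)
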