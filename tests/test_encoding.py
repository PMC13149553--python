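import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from speedcode.encoding import (
    align_by_lag,
    fit_linear_and_compare,
    fit_single_phase,
    fit_single_phase_inverse,
    inverse_single_phase,
    normalize_population,
    parameter_relations,
    peak_to_peak_fit,
    single_phase,
)
from speedcode.ccf import cross_correlation


def _noisy_curve(f0, vm, tau, n=100, noise=0.0, seed=0, span=3.0):
    rng = np.random.default_rng(seed)
    f = np.linspace(f0, f0 + span * tau, n)
    v = single_phase(f, f0, vm, tau) + rng.normal(0, noise, n)
    return f, np.clip(v, 0, None)


class TestAlignByLag:
    def test_zero_lag_identity(self, rng):
        f, v = rng.normal(size=50), rng.normal(size=50)
        fa, va = align_by_lag(f, v, 0.0)
        np.testing.assert_array_equal(fa, f)
        np.testing.assert_array_equal(va, v)

    def test_alignment_improves_zero_lag_correlation(self, rng):
        base = np.cumsum(rng.normal(size=850))
        firing = base[50:]
        speed = base[:800]
        before = np.corrcoef(firing, speed)[0, 1]
        fa, va = align_by_lag(firing, speed, 5.0, bin_width=0.1)
        after = np.corrcoef(fa, va)[0, 1]
        assert after >= before

    def test_realigned_series_has_zero_optimal_lag(self, rng):
        base = np.cumsum(rng.normal(size=830))
        firing, speed = base[30:], base[:800]
        fa, va = align_by_lag(firing, speed, 3.0, bin_width=0.1)
        res = cross_correlation(fa, va, lag_max=5.0, bin_width=0.1)
        assert abs(res.lag_star) <= 0.1

    def test_excessive_lag_rejected(self, rng):
        with pytest.raises(ValueError):
            align_by_lag(rng.normal(size=10), rng.normal(size=10), 2.0, 0.1)


class TestSinglePhaseFit:
    def test_noiseless_recovery(self):
        f, v = _noisy_curve(2.0, 30.0, 20.0)
        fit = fit_single_phase(f, v)
        assert fit.converged
        assert fit.f0 == pytest.approx(2.0, abs=1e-6)
        assert fit.v_m == pytest.approx(30.0, rel=1e-6)
        assert fit.tau == pytest.approx(20.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_characteristic_632_point(self):
        # at f = f0 + tau the model reaches 63.2% of v_m
        v = single_phase(np.array([2.0 + 20.0]), 2.0, 30.0, 20.0)[0]
        assert v / 30.0 == pytest.approx(1 - np.exp(-1), abs=1e-12)

    def test_noisy_tau_recovery_median_error(self):
        errs = []
        for s in range(60):
            f, v = _noisy_curve(2.0, 30.0, 20.0, noise=0.05 * 30.0, seed=s)
            fit = fit_single_phase(f, v, seed=s)
            errs.append(abs(fit.tau - 20.0) / 20.0)
        assert np.median(errs) < 0.10

    def test_too_few_distinct_rates_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_single_phase(np.array([1.0, 1.0, 2.0, 2.0]), np.ones(4))

    def test_negative_speed_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_single_phase(np.arange(6.0), np.array([1, 2, 3, -1, 4, 5.0]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_forward_model_identity_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        f0, tau, vm = rng.uniform(0, 10), rng.uniform(5, 40), rng.uniform(5, 40)
        f, v = _noisy_curve(f0, vm, tau, seed=seed)
        fit = fit_single_phase(f, v, seed=seed)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.v_m == pytest.approx(vm, rel=1e-6)

    def test_invariant_to_pair_order(self, rng):
        f, v = _noisy_curve(1.0, 25.0, 15.0, noise=0.5, seed=4)
        perm = rng.permutation(f.size)
        a = fit_single_phase(f, v)
        b = fit_single_phase(f[perm], v[perm])
        assert a.tau == pytest.approx(b.tau, rel=1e-6)


class TestInverseFit:
    def test_noiseless_recovery_matches_forward(self):
        v = np.linspace(0, 29.0, 80)
        f = inverse_single_phase(v, 2.0, 30.0, 20.0)
        fit = fit_single_phase_inverse(v, f)
        assert fit.converged
        assert fit.f0 == pytest.approx(2.0, abs=1e-5)
        assert fit.v_m == pytest.approx(30.0, rel=1e-5)
        assert fit.tau == pytest.approx(20.0, rel=1e-5)

    def test_less_biased_than_forward_under_firing_noise(self):
        """With counting noise on the firing axis, regressing firing on
        speed recovers tau; regressing speed on firing inflates it."""
        rng = np.random.default_rng(0)
        tau_inv, tau_fwd = [], []
        for s in range(20):
            v = np.concatenate([np.zeros(100), rng.uniform(0, 25, 200)])
            f_true = inverse_single_phase(v, 2.0, 28.0, 15.0)
            f_obs = rng.poisson(np.maximum(f_true, 0) * 0.1) / 0.1  # 0.1 s bins
            tau_inv.append(fit_single_phase_inverse(v, f_obs, seed=s).tau)
            tau_fwd.append(fit_single_phase(f_obs, v, seed=s).tau)
        assert abs(np.median(tau_inv) - 15.0) < abs(np.median(tau_fwd) - 15.0)
        assert np.median(tau_inv) == pytest.approx(15.0, rel=0.25)

    def test_same_curve_both_directions(self):
        v = np.linspace(0, 25, 50)
        f = inverse_single_phase(v, 1.0, 26.0, 12.0)
        back = single_phase(f, 1.0, 26.0, 12.0)
        np.testing.assert_allclose(back, v, atol=1e-9)


class TestModelComparison:
    def test_linear_data_prefers_linear(self, rng):
        f = np.linspace(0, 50, 80)
        v = 0.5 * f + rng.normal(0, 0.1, 80)
        v = np.clip(v, 0, None)
        nl = fit_single_phase(f, v)
        out = fit_linear_and_compare(f, v, nl)
        assert out["delta_r_squared"] <= 0.01
        assert out["preferred"] == "linear"

    def test_saturating_data_prefers_nonlinear(self):
        f, v = _noisy_curve(2.0, 25.0, 10.0, noise=0.5, seed=2, span=4.0)
        nl = fit_single_phase(f, v)
        out = fit_linear_and_compare(f, v, nl)
        assert out["delta_r_squared"] > 0
        assert out["preferred"] == "single_phase"

    def test_comparison_stable_under_affine_speed_rescale(self):
        f, v = _noisy_curve(2.0, 25.0, 10.0, noise=0.5, seed=3, span=4.0)
        nl1 = fit_single_phase(f, v)
        d1 = fit_linear_and_compare(f, v, nl1)["delta_r_squared"]
        v2 = 2.5 * v
        nl2 = fit_single_phase(f, v2)
        d2 = fit_linear_and_compare(f, v2, nl2)["delta_r_squared"]
        assert d1 == pytest.approx(d2, abs=1e-6)


class TestPeakToPeak:
    def test_shared_curve_recovered(self, rng):
        peaks_f = rng.uniform(10, 60, 25)
        peaks_v = single_phase(peaks_f, 2.0, 30.0, 15.0) + rng.normal(0, 0.5, 25)
        fit, comp = peak_to_peak_fit(peaks_f, np.clip(peaks_v, 0, None))
        assert fit.converged
        assert fit.tau == pytest.approx(15.0, rel=0.25)
        assert fit.v_m == pytest.approx(30.0, rel=0.15)

    def test_identical_peaks_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            peak_to_peak_fit(np.full(8, 20.0), np.full(8, 10.0))

    def test_point_on_curve_leaves_fit_unchanged(self):
        f, v = _noisy_curve(2.0, 30.0, 20.0, n=50)
        fit1, _ = peak_to_peak_fit(f, v)
        f_new = np.r_[f, 35.0]
        v_new = np.r_[v, single_phase(np.array([35.0]), fit1.f0, fit1.v_m, fit1.tau)]
        fit2, _ = peak_to_peak_fit(f_new, v_new)
        assert fit2.tau == pytest.approx(fit1.tau, rel=1e-6)


class TestNormalization:
    @staticmethod
    def _group(tau, n=10, seed=0, noise_frac=0.03):
        rng = np.random.default_rng(seed)
        fits, pairs, ids = [], [], []
        for i in range(n):
            f0 = rng.uniform(0, 5)
            vm = rng.uniform(15, 35)
            f = np.linspace(f0, f0 + 2.5 * tau, 80)
            v = np.clip(
                single_phase(f, f0, vm, tau) + rng.normal(0, noise_frac * vm, 80),
                0, None,
            )
            fits.append(fit_single_phase(f, v, seed=i))
            pairs.append((f, v))
            ids.append(f"n{i}")
        return fits, pairs, ids

    def test_shared_tau_low_dispersion(self):
        fits, pairs, ids = self._group(10.0, seed=1)
        nf = normalize_population(fits, pairs, ids, group="g")
        assert nf.tau_sd / nf.tau_mean < 0.1

    def test_single_neuron_trivial(self):
        fits, pairs, ids = self._group(12.0, n=1, seed=2, noise_frac=0.0)
        nf = normalize_population(fits, pairs, ids)
        assert nf.tau_refit[0] == pytest.approx(fits[0].tau, rel=0.05)

    def test_tau_ratio_between_groups_preserved(self):
        nf1 = normalize_population(*self._group(10.0, seed=3))
        nf2 = normalize_population(*self._group(20.0, seed=4))
        ratio = nf2.tau_mean / nf1.tau_mean
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_normalization_reduces_tau_dispersion(self):
        fits, pairs, ids = self._group(10.0, seed=5, noise_frac=0.05)
        raw_tau = np.array([ft.tau for ft in fits])
        nf = normalize_population(fits, pairs, ids)
        assert nf.tau_refit.var() < raw_tau.var() + 1e-12


class TestParameterRelations:
    def test_generating_line_recovered(self, rng):
        from speedcode.encoding import EncodingFit
        tau = rng.uniform(5, 30, 40)
        vm = 1.43 * tau + 7.37 + rng.normal(0, 1.0, 40)
        fits = [
            EncodingFit("single_phase", f0=rng.uniform(0, 5), v_m=v, tau=t,
                        converged=True)
            for t, v in zip(tau, vm)
        ]
        out = parameter_relations(fits)
        assert out["vm_on_tau"]["slope"] == pytest.approx(1.43, abs=0.15)
        assert out["vm_on_tau"]["p"] < 1e-6

    def test_independent_parameters_weak_correlation(self, rng):
        from speedcode.encoding import EncodingFit
        fits = [
            EncodingFit("single_phase", f0=rng.uniform(0, 5),
                        v_m=rng.uniform(10, 40), tau=rng.uniform(5, 30),
                        converged=True)
            for _ in range(200)
        ]
        out = parameter_relations(fits)
        assert abs(out["vm_on_tau"]["r"]) < 0.2

    def test_collinear_input_r2_one(self):
        from speedcode.encoding import EncodingFit
        tau = np.linspace(5, 25, 10)
        fits = [
            EncodingFit("single_phase", f0=1.0, v_m=2 * t + 3, tau=t, converged=True)
            for t in tau
        ]
        out = parameter_relations(fits)
        assert out["vm_on_tau"]["r_squared"] == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        from speedcode.encoding import EncodingFit
        fits = [EncodingFit("single_phase", f0=1.0, v_m=10.0 + i, tau=5.0,
                            converged=True) for i in range(6)]
        with pytest.raises(ValueError, match="constant"):
            parameter_relations(fits)
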