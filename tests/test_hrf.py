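import numpy as np
import pytest
from scipy.signal import fftconvolve

from oxyflick.datasets import make_coupled_session, make_fgn
from oxyflick.hrf import (GammaVariateFit, HRFKernel, HRFRegressor,
                          deconvolve_hrf, double_gamma_kernel,
                          fit_double_gamma, gamma_variate, predict_oxygen,
                          smooth_hrf)
from oxyflick.trace import SignalTrace

FS = 20.0


def _physio_kernel(n=200, dt=1 / FS):
    lags = np.arange(n) * dt
    return HRFKernel(double_gamma_kernel(lags, [1.0, 3.0, 4.0,
                                                -0.3, 6.0, 5.0]), dt)


def _noiseless_pair(h, duration=600.0, seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration * FS)
    blp_vals = np.abs(rng.standard_normal(n)) + 0.05
    oxy_vals = fftconvolve(blp_vals, h.values, mode="full")[:n]
    return (SignalTrace(blp_vals, FS), SignalTrace(oxy_vals, FS))


class TestDeconvolution:
    def test_noiseless_roundtrip_is_identity(self):
        h_true = _physio_kernel()
        blp, oxy = _noiseless_pair(h_true)
        h = deconvolve_hrf(blp, oxy, kernel_len=10.0)
        peak = np.abs(h_true.values).max()
        np.testing.assert_allclose(h.values,
                                   h_true.values[:len(h)], atol=1e-6 * peak)

    def test_noisy_recovery_correlates(self):
        h_true = _physio_kernel()
        blp, oxy = _noiseless_pair(h_true, duration=1200.0, seed=3)
        rng = np.random.default_rng(4)
        sd = oxy.values.std() / np.sqrt(10.0)   # SNR 10
        noisy = oxy.with_values(oxy.values + sd * rng.standard_normal(oxy.n))
        h = deconvolve_hrf(blp, noisy, kernel_len=10.0)
        r = np.corrcoef(h.values, h_true.values[:len(h)])[0, 1]
        assert r > 0.95

    def test_impulse_design_reads_off_kernel(self):
        # regressor = sparse unit impulses: the solve reduces to averaging
        # the response after each impulse, i.e. cross-correlation at lag
        n = 4000
        blp_vals = np.zeros(n)
        blp_vals[np.arange(100, n - 300, 400)] = 1.0
        h_true = _physio_kernel(150)
        oxy_vals = fftconvolve(blp_vals, h_true.values, mode="full")[:n]
        h = deconvolve_hrf(SignalTrace(blp_vals, FS),
                           SignalTrace(oxy_vals, FS), kernel_len=7.5)
        np.testing.assert_allclose(h.values, h_true.values[:len(h)],
                                   atol=1e-8)

    def test_constant_regressor_refused(self):
        blp = SignalTrace(np.full(2000, 2.0), FS)
        oxy = SignalTrace(np.zeros(2000) + 1.0, FS)
        with pytest.raises(np.linalg.LinAlgError):
            deconvolve_hrf(blp, oxy, kernel_len=5.0)


class TestSmoothing:
    def test_cubic_passes_unchanged(self):
        t = np.linspace(0, 1, 50)
        h = HRFKernel(0.3 * t ** 3 - t ** 2 + 2 * t - 0.5, dt=1 / FS)
        out = smooth_hrf(h)
        np.testing.assert_allclose(out.values, h.values, atol=1e-9)

    def test_spike_attenuated(self):
        h_vals = np.exp(-np.arange(60) / 10.0)
        h_vals[30] += 1.0
        out = smooth_hrf(HRFKernel(h_vals, dt=1 / FS))
        assert abs(out.values[30] - np.exp(-3.0)) < 0.5

    def test_short_kernel_refused(self):
        with pytest.raises(ValueError):
            smooth_hrf(HRFKernel(np.ones(5), dt=1 / FS))


class TestGammaVariate:
    def test_peak_at_T_with_amplitude_A(self):
        t = np.linspace(0, 20, 2001)
        y = gamma_variate(t, 2.0, 3.0, 4.0)
        assert t[np.argmax(y)] == pytest.approx(3.0, abs=0.02)
        assert y.max() == pytest.approx(2.0, rel=1e-6)

    def test_fwhm_matches_W(self):
        t = np.linspace(0, 30, 30_001)
        y = gamma_variate(t, 1.0, 3.0, 4.0)
        above = t[y >= 0.5]
        # gamma-variate FWHM parameterization is exact to a few percent
        assert above[-1] - above[0] == pytest.approx(4.0, rel=0.05)

    def test_single_lobe_parameters_recovered(self):
        lags = np.arange(300) / FS
        target = HRFKernel(gamma_variate(lags, 1.0, 3.0, 4.0), dt=1 / FS)
        fit = fit_double_gamma(target, restarts=10, seed=1)
        A, T, W = fit.positive_lobe()
        assert A == pytest.approx(1.0, rel=0.02)
        assert T == pytest.approx(3.0, rel=0.02)
        assert W == pytest.approx(4.0, rel=0.02)
        assert fit.r2 > 0.999

    def test_alpha_beta_identities(self):
        fit = GammaVariateFit(A=(1.0, -0.2), T=(3.0, 6.0), W=(4.0, 5.0),
                              r2=1.0, converged=True)
        ln2_8 = 8 * np.log(2)
        for a, b, T, W in zip(fit.alpha, fit.beta, fit.T, fit.W):
            assert a == pytest.approx((T / W) ** 2 * ln2_8)
            assert b == pytest.approx(W ** 2 / (T * ln2_8))
            assert b == pytest.approx(T / a)   # consistency of the two forms

    def test_self_fit_r2_is_one(self):
        lags = np.arange(200) / FS
        k = HRFKernel(double_gamma_kernel(lags, [1.0, 3.0, 4.0, -0.3, 6.0,
                                                 5.0]), dt=1 / FS)
        fit = fit_double_gamma(k, restarts=10, seed=2)
        assert fit.r2 > 0.999


class TestPrediction:
    def test_split_half_noiseless_r2_one(self):
        h = _physio_kernel()
        blp, oxy = make_coupled_session(600.0, h, 0.9, 0.0, seed=5)
        reg = HRFRegressor(kernel_len=12.0)
        assert reg.score_splithalf(blp, oxy) > 0.999

    def test_no_leakage_between_halves(self):
        h = _physio_kernel()
        blp, oxy = make_coupled_session(400.0, h, 0.9, 0.1, seed=6)
        reg = HRFRegressor(kernel_len=10.0)
        reg.score_splithalf(blp, oxy)
        assert reg.train_span_[1] <= reg.test_span_[0]

    def test_noise_dominated_r2(self):
        # noise variance 9x signal variance -> r2 ~ 1/(1+9) = 0.1
        h = _physio_kernel()
        blp, oxy0 = make_coupled_session(2400.0, h, 0.9, 0.0, seed=7)
        noise = make_fgn(oxy0.n, FS, 0.5, seed=8).values
        sd = 3.0 * oxy0.values.std()
        oxy = oxy0.with_values(oxy0.values + sd * noise)
        r2 = HRFRegressor(kernel_len=10.0).score_splithalf(blp, oxy)
        assert r2 == pytest.approx(0.1, abs=0.06)

    def test_zero_kernel_warns_and_returns_zero(self):
        blp = SignalTrace(np.abs(np.random.default_rng(0).standard_normal(400)),
                          FS)
        obs = SignalTrace(np.random.default_rng(1).standard_normal(400), FS)
        h = HRFKernel(np.zeros(40), dt=1 / FS)
        with pytest.warns(UserWarning):
            _, r2 = predict_oxygen(blp, h, observed=obs)
        assert r2 == 0.0
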