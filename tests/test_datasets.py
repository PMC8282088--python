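import numpy as np
import pytest

from oxyflick import datasets
from oxyflick.datasets import fgn_autocovariance
from oxyflick.preprocessing import binarize_locomotion, lowpass_velocity, \
    respiration_rate, segment_rest
from oxyflick.spectral import multitaper_psd


class TestWhiteNoise:
    def test_zero_mean_unit_variance(self):
        tr = datasets.make_white_noise(10 ** 5, 30.0, seed=1)
        n = tr.n
        assert abs(tr.values.mean()) < 3.0 / np.sqrt(n)
        assert abs(tr.values.var() - 1.0) < 0.05

    def test_deterministic_for_fixed_seed(self):
        a = datasets.make_white_noise(1000, 30.0, seed=7)
        b = datasets.make_white_noise(1000, 30.0, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError):
            datasets.make_white_noise(10, 30.0, seed=0)


class TestFGN:
    def test_h05_is_uncorrelated(self):
        tr = datasets.make_fgn(2 ** 15, 30.0, 0.5, seed=3)
        x = tr.values
        lag1 = np.mean(x[:-1] * x[1:]) / x.var()
        assert abs(lag1) < 0.02

    def test_autocovariance_matches_closed_form(self):
        # oracle: gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H)
        tr = datasets.make_fgn(2 ** 17, 30.0, 0.7, seed=3)
        x = tr.values
        lags = np.arange(1, 11)
        emp = np.array([np.mean(x[:-k] * x[k:]) for k in lags])
        thy = fgn_autocovariance(lags, 0.7)
        # Monte-Carlo error on each lag covariance is ~ 1/sqrt(n)
        np.testing.assert_allclose(emp, thy, atol=5.0 / np.sqrt(x.size))

    def test_unit_variance(self):
        # oracle SE of the sample variance of a correlated Gaussian series:
        # Var(s^2) ~ (2/n) * sum_k (1-|k|/n) gamma(k)^2 (long-range terms
        # dominate for H near 1, so the naive sqrt(2/n) is far too tight)
        n = 2 ** 14
        tr = datasets.make_fgn(n, 30.0, 0.9, seed=4)
        k = np.arange(1, n)
        g2 = fgn_autocovariance(k, 0.9) ** 2
        se = np.sqrt(2.0 / n * (1.0 + 2.0 * np.sum((1 - k / n) * g2)))
        assert abs(tr.values.var() - 1.0) < 3 * se

    def test_rejects_bad_hurst(self):
        with pytest.raises(ValueError):
            datasets.make_fgn(1024, 30.0, 1.5, seed=0)


class TestPeriodic:
    def test_psd_peaks_at_f0(self):
        tr = datasets.make_periodic(2 ** 14, 30.0, 0.2, noise_sd=0.0, seed=0)
        ps = multitaper_psd(tr)
        assert abs(ps.freqs[np.argmax(ps.power)] - 0.2) < 0.01

    def test_noiseless_amplitude(self):
        tr = datasets.make_periodic(2 ** 12, 30.0, 0.2, noise_sd=0.0, seed=0,
                                    amplitude=2.5)
        assert abs(tr.values.max() - 2.5) < 0.01

    def test_peak_exceeds_noise_floor(self):
        tr = datasets.make_periodic(2 ** 15, 30.0, 0.2, noise_sd=1.0, seed=1)
        ps = multitaper_psd(tr)
        peak = ps.power[np.argmin(np.abs(ps.freqs - 0.2))]
        off = (ps.freqs > 1.0) & (ps.freqs < 10.0)
        assert peak > 10 * np.median(ps.power[off])

    def test_rejects_aliasing(self):
        with pytest.raises(ValueError):
            datasets.make_periodic(1024, 30.0, 20.0, noise_sd=0.0, seed=0)


class TestHybrid:
    def test_mix_zero_equals_fgn(self):
        a = datasets.make_hybrid(2 ** 12, 30.0, 0.9, 0.2, mix=0.0, seed=5)
        b = datasets.make_fgn(2 ** 12, 30.0, 0.9, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_power_law_fit_residual_positive_at_bump(self):
        from oxyflick.spectral import fit_power_law, log_resample

        tr = datasets.make_hybrid(2 ** 17, 30.0, 0.9, 0.2, mix=1.0, seed=6)
        ps = log_resample(multitaper_psd(tr), band=(0.01, 1.0))
        fit = fit_power_law(ps)
        assert fit.beta > 0.3  # negative log-log slope from the fGn part
        model = 10 ** (fit.intercept - fit.beta * np.log10(ps.freqs))
        i_bump = np.argmin(np.abs(ps.freqs - 0.2))
        assert ps.power[i_bump] > model[i_bump]  # local bump above the line


class TestBehaviorSession:
    def test_no_bouts_means_quiet_accel(self):
        _, acc = datasets.make_behavior_session(300.0, 30.0, bout_rate=0.0,
                                                seed=0)
        assert np.all(np.abs(acc.values) < 1e-9)

    def test_flags_cover_known_bouts(self):
        vel, acc = datasets.make_behavior_session(600.0, 30.0, bout_rate=2.0,
                                                  seed=3)
        accel = lowpass_velocity(vel)
        a = accel.with_values(
            np.concatenate([[0.0], np.diff(accel.values)]) * 30.0)
        mask = binarize_locomotion(a)
        t = vel.times
        truth = np.zeros(vel.n, dtype=bool)
        for s, e in vel.meta["bouts"]:
            truth |= (t >= s) & (t < e)
        assert truth.any()
        # every ground-truth bout must intersect flagged samples
        overlap = np.mean(mask.flags[truth] == 1)
        # bouts are flagged at onset/offset transients, not plateaus
        for s, e in vel.meta["bouts"]:
            seg = (t >= s - 0.5) & (t < e + 0.5)
            assert mask.flags[seg].any()

    def test_close_bouts_leave_no_rest(self):
        # two bouts 3 s apart violate the 4-s post-locomotion buffer
        fs = 30.0
        n = int(300 * fs)
        flags = np.zeros(n, dtype=int)
        flags[int(100 * fs):int(102 * fs)] = 1
        flags[int(105 * fs):int(107 * fs)] = 1
        from oxyflick.preprocessing import BehaviorMask

        segs = segment_rest(BehaviorMask(flags, fs, 3.0))
        for seg in segs:
            assert not (102.0 < seg.start < 105.0)


class TestCoupledSession:
    def test_noiseless_r2_is_one(self):
        from oxyflick.hrf import HRFKernel, HRFRegressor

        h = HRFKernel(np.exp(-np.arange(100) / 20.0), dt=0.05)
        blp, oxy = datasets.make_coupled_session(600.0, h, 0.9, 0.0, seed=8)
        r2 = HRFRegressor(kernel_len=10.0).score_splithalf(blp, oxy)
        assert r2 > 0.999

    def test_blp_non_negative(self):
        from oxyflick.hrf import HRFKernel

        h = HRFKernel(np.exp(-np.arange(100) / 20.0), dt=0.05)
        blp, _ = datasets.make_coupled_session(300.0, h, 0.9, 0.5, seed=9)
        assert np.all(blp.values >= 0)

    def test_r2_matches_variance_fraction(self):
        # oracle: r2 = var(signal) / (var(signal) + var(noise))
        from scipy.signal import fftconvolve

        from oxyflick.hrf import HRFKernel, HRFRegressor

        h = HRFKernel(np.exp(-np.arange(100) / 20.0), dt=0.05)
        blp, oxy0 = datasets.make_coupled_session(1200.0, h, 0.9, 0.0, seed=10)
        signal = oxy0.values
        noise = datasets.make_fgn(oxy0.n, 20.0, 0.9, seed=11).values
        target_frac = 0.5
        sd = np.sqrt(signal.var() * (1 - target_frac) / target_frac)
        oxy = oxy0.with_values(signal + sd * noise)
        r2 = HRFRegressor(kernel_len=10.0).score_splithalf(blp, oxy)
        assert abs(r2 - target_frac) < 0.15


class TestRespiration:
    def test_constant_rate_recovered(self):
        tr = datasets.make_respiration(120.0, 100.0, rate=3.0,
                                       rate_jitter=0.0, seed=0)
        peaks, rate = respiration_rate(tr)
        assert rate is not None
        mid = rate.values[rate.n // 4: 3 * rate.n // 4]
        np.testing.assert_allclose(mid, 3.0, rtol=0.05)

    def test_jittered_peaks_match_ground_truth(self):
        tr = datasets.make_respiration(120.0, 100.0, rate=2.0,
                                       rate_jitter=0.1, seed=4)
        peaks, _ = respiration_rate(tr)
        truth = np.asarray(tr.meta["peak_times"])
        # match each true peak to the nearest detection
        for t in truth[1:-1]:
            assert np.min(np.abs(peaks - t)) <= 1.5 / tr.sampling_rate

    def test_constant_input_has_no_peaks(self):
        from oxyflick.trace import SignalTrace

        tr = SignalTrace(np.linspace(0, 1, 200), 10.0)  # monotone ramp
        with pytest.warns(UserWarning):
            peaks, rate = respiration_rate(tr)
        assert peaks.size == 0 and rate is None
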