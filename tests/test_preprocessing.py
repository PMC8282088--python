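import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxyflick.preprocessing import (BehaviorMask, CalibrationPair,
                                    binarize_locomotion, correct_drift,
                                    extract_blp, filter_lfp_mua,
                                    preprocess_oxygen, respiration_rate,
                                    segment_rest, spike_rate)
from oxyflick.trace import SignalTrace


def _sine(freq, fs, duration, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalTrace(amp * np.sin(2 * np.pi * freq * t), fs)


class TestLocomotion:
    def test_zero_accel_gives_zero_mask(self):
        tr = SignalTrace(np.zeros(100) + 1e-12, 30.0)
        assert binarize_locomotion(tr).flags.sum() == 0

    def test_threshold_is_inclusive(self):
        tr = SignalTrace(np.array([0.0, 3.0, -3.0, 2.999]), 30.0)
        mask = binarize_locomotion(tr, a_c=3.0)
        np.testing.assert_array_equal(mask.flags, [0, 1, 1, 0])


def _brute_force_rest(flags, fs, min_gap, min_len):
    """Enumerate qualifying rest windows sample by sample."""
    segments = []
    n = flags.size
    i = 0
    last_loco = -1
    while i <= n:
        if i == n or flags[i] == 1:
            quiet_start = last_loco + 1
            if i - quiet_start >= 1:
                start = quiet_start / fs + min_gap
                end = i / fs
                if end - start >= min_len:
                    segments.append((start, end))
            last_loco = i
        i += 1
    return segments


class TestSegmentRest:
    def test_quiet_trace_gives_one_guarded_segment(self):
        fs = 30.0
        mask = BehaviorMask(np.zeros(int(120 * fs), dtype=int), fs, 3.0)
        segs = segment_rest(mask)
        assert len(segs) == 1
        assert segs[0].start == pytest.approx(4.0)
        assert segs[0].end == pytest.approx(120.0)

    def test_70s_gap_survives_buffer(self):
        fs = 10.0
        flags = np.zeros(int(200 * fs), dtype=int)
        flags[int(50 * fs)] = 1          # locomotion at 50 s
        flags[int(120.1 * fs)] = 1       # next at 120.1 s -> ~70-s quiet gap
        segs = segment_rest(BehaviorMask(flags, fs, 3.0))
        inner = [s for s in segs if 50 < s.start < 120]
        assert len(inner) == 1
        assert inner[0].duration >= 60.0

    def test_50s_gap_rejected(self):
        fs = 10.0
        flags = np.ones(int(200 * fs), dtype=int)
        flags[int(100 * fs):int(150 * fs)] = 0   # 50-s quiet gap
        assert segment_rest(BehaviorMask(flags, fs, 3.0)) == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=10, max_size=400))
    def test_matches_brute_force_enumeration(self, bits):
        fs = 2.0
        flags = np.asarray(bits, dtype=int)
        got = segment_rest(BehaviorMask(flags, fs, 3.0), min_gap=1.0,
                           min_len=5.0)
        want = _brute_force_rest(flags, fs, 1.0, 5.0)
        assert [(s.start, s.end) for s in got] == pytest.approx(want)


class TestOxygenPreprocessing:
    def test_deep_passband_amplitude_preserved(self):
        tr = _sine(0.05, 1000.0, 200.0)
        out = preprocess_oxygen(tr)
        assert out.sampling_rate == 30.0
        mid = out.values[out.n // 4: 3 * out.n // 4]
        assert abs(mid.max() - 1.0) < 0.01

    def test_stopband_attenuated(self):
        tr = _sine(5.0, 1000.0, 60.0)
        out = preprocess_oxygen(tr)
        mid = out.values[out.n // 4: 3 * out.n // 4]
        assert mid.max() < 0.05  # > 95 % attenuation at 5x cutoff

    def test_constant_passes_through(self):
        tr = SignalTrace(np.full(6000, 7.5), 600.0)
        out = preprocess_oxygen(tr)
        np.testing.assert_allclose(out.values, 7.5, rtol=1e-6)

    def test_low_rate_refused(self):
        tr = SignalTrace(np.zeros(100) + 1.0, 30.0)
        with pytest.raises(ValueError):
            preprocess_oxygen(tr)


class TestDriftCorrection:
    def test_identical_calibrations_are_static(self):
        cal = CalibrationPair(pre=((0.0, 0.0), (1.0, 160.0)),
                              post=((0.0, 0.0), (1.0, 160.0)),
                              session_duration=2.0)
        tr = SignalTrace(np.linspace(0.1, 0.9, 100), 30.0)
        out = correct_drift(tr, cal)
        np.testing.assert_allclose(out.values, tr.values * 160.0)

    def test_injected_gain_drift_removed(self):
        # 2 %/h sensitivity loss over a 2-h session on a constant-PO2 input
        fs, hours = 30.0, 2.0
        n = int(hours * 3600 * fs)
        true_po2 = 30.0
        gain0 = 1.0 / 160.0
        drift = 1.0 - 0.02 * np.linspace(0, hours, n)
        current = true_po2 * gain0 * drift
        cal = CalibrationPair(
            pre=((0.0, 0.0), (gain0 * 160.0, 160.0)),
            post=((0.0, 0.0), (gain0 * drift[-1] * 160.0, 160.0)),
            session_duration=hours)
        out = correct_drift(SignalTrace(current, fs), cal)
        np.testing.assert_allclose(out.values, true_po2, rtol=1e-3)

    def test_zero_current_maps_to_zero_anchor(self):
        cal = CalibrationPair(pre=((0.0, 0.0), (1.0, 160.0)),
                              post=((0.0, 0.0), (0.9, 160.0)),
                              session_duration=1.0)
        out = correct_drift(SignalTrace(np.zeros(50) + 0.0, 30.0), cal)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPair(pre=((0.5, 0.0), (0.5, 160.0)),
                            post=((0.0, 0.0), (1.0, 160.0)),
                            session_duration=1.0)


class TestLFPMUASplit:
    def test_band_membership(self):
        fs = 20_000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 1000 * t)
        lfp, mua = filter_lfp_mua(SignalTrace(x, fs))
        # 60 Hz lives in LFP; 1 kHz in MUA
        def amp_at(trace, f):
            spec = np.abs(np.fft.rfft(trace.values * np.hanning(trace.n)))
            freqs = np.fft.rfftfreq(trace.n, 1 / fs)
            return spec[np.argmin(np.abs(freqs - f))]

        assert amp_at(lfp, 60) > 100 * amp_at(mua, 60)
        assert amp_at(mua, 1000) > 100 * amp_at(lfp, 1000)

    def test_low_rate_refused(self):
        with pytest.raises(ValueError):
            filter_lfp_mua(SignalTrace(np.zeros(100) + 1.0, 1000.0))


class TestBLP:
    def test_am_envelope_recovered(self):
        # 60-Hz carrier amplitude-modulated at 0.1 Hz -> gamma BLP at 0.1 Hz
        fs = 1000.0
        t = np.arange(int(120 * fs)) / fs
        x = (1.0 + 0.8 * np.sin(2 * np.pi * 0.1 * t)) * np.sin(2 * np.pi * 60 * t)
        blp = extract_blp(SignalTrace(x, fs), "gamma")
        assert blp.sampling_rate == 20.0
        assert np.all(blp.values >= 0)
        from oxyflick.spectral import multitaper_psd

        ps = multitaper_psd(blp)
        inband = (ps.freqs > 0.02) & (ps.freqs < 1.0)
        f_peak = ps.freqs[inband][np.argmax(ps.power[inband])]
        assert abs(f_peak - 0.1) < 0.03

    def test_out_of_band_carrier_suppressed(self):
        blp = extract_blp(_sine(5.0, 1000.0, 30.0), "gamma")
        assert blp.values.max() < 1e-3

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            extract_blp(_sine(60.0, 1000.0, 10.0), "delta")


class TestSpikeRate:
    def test_injected_spikes_counted(self, rng):
        # paired design: identical background noise with and without the
        # injected events isolates the event count from the noise-crossing
        # rate of the 3-SD threshold
        fs = 20_000.0
        n = int(10 * fs)
        noise = rng.standard_normal(n)
        sd = noise.std()
        idx = rng.choice(np.arange(1000, n - 1000), size=50, replace=False)
        idx.sort()
        idx = idx[np.concatenate([[True], np.diff(idx) > 100])]
        with_spikes = noise.copy()
        with_spikes[idx] += 10 * sd
        duration = n / fs
        rate_with = spike_rate(SignalTrace(with_spikes, fs))
        rate_without = spike_rate(SignalTrace(noise, fs))
        extra = (rate_with.values.mean() - rate_without.values.mean()) * duration
        assert abs(extra - idx.size) < 0.1 * idx.size + 2

    def test_silent_trace_is_zero(self):
        tr = SignalTrace(np.zeros(20_000) + 0.0, 20_000.0)
        rate = spike_rate(tr)
        assert np.all(rate.values == 0)

    def test_gaussian_noise_crossing_rate(self, rng):
        # oracle: Monte-Carlo upward-crossing rate of a 3-SD threshold
        fs = 20_000.0
        x = rng.standard_normal(int(20 * fs))
        rate = spike_rate(SignalTrace(x, fs))
        above = x >= 3 * 1.4826 * np.median(np.abs(x - np.median(x)))
        crossings = np.sum(above[1:] & ~above[:-1])
        measured = rate.values.mean() * 20.0
        assert abs(measured - crossings) < 0.05 * crossings + 5


class TestZeroPhase:
    def test_symmetric_pulse_stays_symmetric(self):
        fs = 1000.0
        n = int(20 * fs)
        x = np.exp(-0.5 * ((np.arange(n) - n // 2) / (0.2 * fs)) ** 2)
        out = preprocess_oxygen(SignalTrace(x, fs))
        peak = np.argmax(out.values)
        left = out.values[peak - 50:peak]
        right = out.values[peak + 1:peak + 51][::-1]
        np.testing.assert_allclose(left, right, atol=5e-3)
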