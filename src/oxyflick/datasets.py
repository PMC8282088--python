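"""Synthetic signal generators with known ground truth.

Every generator returns :class:`~oxyflick.trace.SignalTrace` objects whose
``meta`` field records the generating parameters (kind, Hurst exponent,
target spectral exponent, oscillation frequency, seed), so downstream
estimators can be validated against what was actually simulated:

* white Gaussian noise — spectral exponent beta = 0, DFA alpha = 0.5;
* fractional Gaussian noise (fGn) by exact-covariance circulant embedding —
  DFA alpha = H, spectral beta = 2H - 1;
* a periodic signal (sinusoid + white noise) — a band-limited spectral bump;
* the hybrid sum of the two — 1/f-like slope plus a local bump;
* treadmill-like locomotion sessions with known bout times;
* a neural band-power trace and the oxygen trace obtained by convolving it
  with a known hemodynamic response kernel plus fGn noise;
* a thermocouple-like respiration waveform with known expiratory-peak times.

Functions follow sklearn's ``make_*`` naming; ``gen_*`` aliases are exported
for symmetry with the rest of the library.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .trace import SignalTrace

__all__ = [
    "fgn_autocovariance",
    "make_white_noise",
    "make_fgn",
    "make_periodic",
    "make_hybrid",
    "make_behavior_session",
    "make_coupled_session",
    "make_respiration",
    # gen_* aliases for the generator names used across the library
    "gen_white_noise",
    "gen_fgn",
    "gen_periodic",
    "gen_hybrid",
    "gen_behavior_session",
    "gen_coupled_session",
    "gen_respiration",
]

_MIN_N = 16


def _check_n(n: int) -> int:
    n = int(n)
    if n < _MIN_N:
        raise ValueError(f"need n >= {_MIN_N}, got {n}")
    return n


def make_white_noise(n: int, fs: float, seed: int) -> SignalTrace:
    """I.i.d. standard-normal samples: flat spectrum (beta=0), DFA alpha=0.5."""
    n = _check_n(n)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    return SignalTrace(x, sampling_rate=fs, units="a.u.",
                       meta={"kind": "white", "seed": int(seed)})


def fgn_autocovariance(k: np.ndarray | int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(k) of unit-variance fGn with Hurst exponent H.

    gamma(k) = 0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H)
    """
    k = np.abs(np.atleast_1d(np.asarray(k, dtype=float)))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def make_fgn(n: int, fs: float, hurst: float, seed: int) -> SignalTrace:
    """Exact-covariance fractional Gaussian noise via circulant embedding.

    The length-n target covariance is embedded in a circulant matrix of size
    2m (m = next power of two >= n) whose eigenvalues are the real FFT of the
    first row; a complex Gaussian vector shaped by the eigenvalue square roots
    and inverse-transformed yields two independent exact draws, of which the
    first is returned.  For 0 < H < 1 the embedding of the fGn covariance is
    provably nonnegative definite; a negative eigenvalue beyond roundoff is
    reported rather than clipped silently.
    """
    n = _check_n(n)
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must lie in (0, 1), got {hurst}")
    rng = np.random.default_rng(seed)

    m = 1 << (int(n - 1).bit_length())  # next power of two >= n
    # first row of the circulant embedding: gamma(0..m), gamma(m-1..1)
    row = np.concatenate([
        fgn_autocovariance(np.arange(m + 1), hurst),
        fgn_autocovariance(np.arange(m - 1, 0, -1), hurst),
    ])
    lam = np.fft.fft(row).real
    tol = -1e-8 * np.max(lam)
    if np.any(lam < tol):
        raise ArithmeticError(
            f"circulant embedding not nonnegative definite for H={hurst}: "
            f"min eigenvalue {lam.min():.3e}")
    lam = np.clip(lam, 0.0, None)

    z = rng.standard_normal(2 * m) + 1j * rng.standard_normal(2 * m)
    w = np.fft.fft(np.sqrt(lam / (2 * m)) * z)
    x = w.real[:n]
    return SignalTrace(x, sampling_rate=fs, units="a.u.",
                       meta={"kind": "fgn", "hurst": float(hurst),
                             "beta_true": 2.0 * hurst - 1.0, "seed": int(seed)})


def make_periodic(n: int, fs: float, f0: float, noise_sd: float, seed: int,
                  amplitude: float = 1.0) -> SignalTrace:
    """Sinusoid at f0 Hz plus additive white Gaussian noise."""
    n = _check_n(n)
    if not 0.0 < f0 < fs / 2.0:
        raise ValueError(f"f0 must lie in (0, fs/2)={fs / 2}, got {f0} (aliasing)")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * f0 * t)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
    return SignalTrace(x, sampling_rate=fs, units="a.u.",
                       meta={"kind": "periodic", "f0": float(f0),
                             "noise_sd": float(noise_sd), "seed": int(seed)})


def make_hybrid(n: int, fs: float, hurst: float, f0: float, mix: float,
                seed: int) -> SignalTrace:
    """fGn plus a sinusoid of amplitude ``mix`` (relative to unit-variance fGn).

    ``mix=0`` reduces to :func:`make_fgn` with the same seed.
    """
    base = make_fgn(n, fs, hurst, seed)
    t = np.arange(n) / fs
    x = base.values + mix * np.sin(2 * np.pi * f0 * t)
    if not 0.0 < f0 < fs / 2.0:
        raise ValueError(f"f0 must lie in (0, fs/2), got {f0}")
    return SignalTrace(x, sampling_rate=fs, units="a.u.",
                       meta={"kind": "hybrid", "hurst": float(hurst),
                             "beta_true": 2.0 * hurst - 1.0, "f0": float(f0),
                             "mix": float(mix), "seed": int(seed)})


def make_behavior_session(duration: float, fs: float, bout_rate: float,
                          seed: int, bout_len: tuple[float, float] = (2.0, 10.0),
                          peak_speed: float = 10.0,
                          ) -> tuple[SignalTrace, SignalTrace]:
    """Treadmill-like velocity/acceleration with known locomotion bouts.

    Bouts arrive as a Poisson process at ``bout_rate`` events/min, each a
    half-cosine-onset plateau (smooth enough that the 10-Hz velocity low-pass
    of the preprocessing chain is a no-op on the bout shape).  Velocity is
    cm/s; acceleration is the first difference times fs, cm/s^2.  Ground-truth
    bout windows are stored in ``meta['bouts']`` of both traces.
    """
    if duration < 120.0:
        raise ValueError("behavior sessions must last at least 120 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = np.zeros(n)
    bouts: list[tuple[float, float]] = []
    n_bouts = rng.poisson(bout_rate * duration / 60.0)
    starts = np.sort(rng.uniform(0.0, duration, size=n_bouts))
    ramp = 0.5  # half-cosine ramp time, s
    for s in starts:
        length = rng.uniform(*bout_len)
        e = min(s + length, duration)
        if bouts and s < bouts[-1][1] + 1.0:  # merge near-overlapping bouts
            s = bouts[-1][0]
            bouts[-1] = (s, max(e, bouts[-1][1]))
        else:
            bouts.append((s, e))
    for s, e in bouts:
        seg = (t >= s) & (t < e)
        tt = t[seg] - s
        env = np.ones(tt.size)
        env[tt < ramp] = 0.5 * (1 - np.cos(np.pi * tt[tt < ramp] / ramp))
        tail = (e - s) - tt
        env[tail < ramp] = np.minimum(
            env[tail < ramp], 0.5 * (1 - np.cos(np.pi * tail[tail < ramp] / ramp)))
        v[seg] = peak_speed * env
    a = np.concatenate([[0.0], np.diff(v)]) * fs
    meta = {"kind": "behavior", "bouts": [list(b) for b in bouts],
            "seed": int(seed)}
    vel = SignalTrace(v, sampling_rate=fs, units="cm/s", meta=meta)
    acc = SignalTrace(a, sampling_rate=fs, units="cm/s^2", meta=dict(meta))
    return vel, acc


def make_coupled_session(duration: float, hrf_true, noise_hurst: float,
                         noise_sd: float, seed: int, fs: float = 20.0,
                         ) -> tuple[SignalTrace, SignalTrace]:
    """A band-limited-power trace and the oxygen trace it linearly predicts.

    ``oxy = blp (*) hrf_true + fGn noise``.  The regressor is rectified
    low-passed Gaussian noise (non-negative, spectrally colored like a real
    power envelope); the kernel is a known impulse response on the same 20-Hz
    grid (an :class:`~oxyflick.hrf.HRFKernel` or a bare array).  Ground truth
    (kernel, noise parameters) is stored in the oxygen trace's ``meta``.
    """
    h = np.asarray(getattr(hrf_true, "values", hrf_true), dtype=float)
    n = int(round(duration * fs))
    if not h.size < n / 4:
        raise ValueError("kernel must be shorter than a quarter of the record")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(n)
    sos = signal.butter(3, 1.0, btype="low", fs=fs, output="sos")
    blp_vals = np.abs(signal.sosfiltfilt(sos, raw)) + 0.05
    oxy_vals = signal.fftconvolve(blp_vals, h, mode="full")[:n]
    if noise_sd > 0:
        noise = make_fgn(n, fs, noise_hurst, seed + 1).values
        oxy_vals = oxy_vals + noise_sd * noise
    meta = {"kind": "coupled", "hrf_true": h.tolist(),
            "noise_hurst": float(noise_hurst), "noise_sd": float(noise_sd),
            "seed": int(seed)}
    blp = SignalTrace(blp_vals, sampling_rate=fs, units="a.u.",
                      meta={"kind": "blp_fixture", "seed": int(seed)})
    oxy = SignalTrace(oxy_vals, sampling_rate=fs, units="mmHg", meta=meta)
    return blp, oxy


def make_respiration(duration: float, fs: float, rate: float,
                     rate_jitter: float, seed: int) -> SignalTrace:
    """Quasi-periodic thermocouple-like waveform with known expiratory peaks.

    Breath durations are drawn as 1/rate with multiplicative jitter; the
    waveform is a smooth cosine per breath cycle, so each cycle has exactly
    one expiratory peak, whose times are stored in ``meta['peak_times']``.
    """
    if not 0 < rate < fs / 2:
        raise ValueError("breathing rate must lie in (0, fs/2)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # breath boundaries
    edges = [0.0]
    while edges[-1] < duration:
        period = (1.0 / rate) * np.exp(rate_jitter * rng.standard_normal())
        edges.append(edges[-1] + max(period, 2.0 / fs))
    edges_arr = np.asarray(edges)
    x = np.zeros(n)
    peaks: list[float] = []
    for s, e in zip(edges_arr[:-1], edges_arr[1:]):
        seg = (t >= s) & (t < e)
        if not np.any(seg):
            continue
        phase = (t[seg] - s) / (e - s)
        x[seg] = -np.cos(2 * np.pi * phase)  # peak at mid-cycle
        peak_t = s + 0.5 * (e - s)
        if peak_t < duration:
            peaks.append(peak_t)
    return SignalTrace(x, sampling_rate=fs, units="a.u.",
                       meta={"kind": "respiration", "rate": float(rate),
                             "peak_times": peaks, "seed": int(seed)})


# gen_* aliases
gen_white_noise = make_white_noise
gen_fgn = make_fgn
gen_periodic = make_periodic
gen_hybrid = make_hybrid
gen_behavior_session = make_behavior_session
gen_coupled_session = make_coupled_session
gen_respiration = make_respiration
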