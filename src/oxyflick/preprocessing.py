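"""Signal conditioning for oxygen, electrophysiology and behavior records.

The chain mirrors standard awake-rodent neurovascular practice:

* tissue-oxygen traces: 1-Hz fifth-order Butterworth low-pass, then
  downsampling to 30 Hz; electrode drift corrected by linear interpolation
  between pre- and post-session two-point calibrations;
* neural broadband: LFP (0.1-300 Hz) / MUA (300-3000 Hz) fifth-order
  band-passes; band-limited power (BLP) by third-order zero-phase band-pass
  (sub-alpha 1-8, beta 10-30, gamma 40-100 Hz), squaring and full-wave
  rectification, <1 Hz low-pass and resampling to 20 Hz; spike rate by 3-SD
  threshold crossings in 1-ms bins smoothed with a 10-ms-FWHM Gaussian;
* behavior: locomotion flagged where |acceleration| >= 3 cm/s^2 (velocity
  first low-passed at 10 Hz); rest segments are quiet periods starting at
  least 4 s after the last locomotion sample and lasting >= 60 s;
* respiration: expiratory peaks at negative-going zero crossings of the
  thermocouple derivative; instantaneous rate as reciprocal inter-peak
  intervals on a uniform grid.

All Butterworth filters are applied forward-backward (zero phase): the
spectral and envelope analyses downstream are phase-agnostic, and symmetric
application preserves event timing.  The effective filter order is therefore
doubled relative to the nominal one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .trace import SignalTrace

__all__ = [
    "BehaviorMask", "RestSegment", "CalibrationPair", "BLP_BANDS",
    "binarize_locomotion", "segment_rest", "preprocess_oxygen",
    "correct_drift", "filter_lfp_mua", "extract_blp", "spike_rate",
    "respiration_rate", "lowpass_velocity", "resample_trace",
]

BLP_BANDS = {
    "sub_alpha": (1.0, 8.0),
    "beta": (10.0, 30.0),
    "gamma": (40.0, 100.0),
}

ACCEL_THRESHOLD = 3.0        # cm/s^2
REST_MIN_GAP = 4.0           # s after locomotion offset
REST_MIN_LEN = 60.0          # s


@dataclass(frozen=True)
class BehaviorMask:
    flags: np.ndarray          # {0,1}, aligned to the source trace
    sampling_rate: float
    threshold_used: float

    def __post_init__(self) -> None:
        f = np.asarray(self.flags, dtype=int)
        if not np.isin(f, (0, 1)).all():
            raise ValueError("mask flags must be 0 or 1")
        object.__setattr__(self, "flags", f)

    def __len__(self) -> int:
        return self.flags.size


@dataclass(frozen=True)
class RestSegment:
    start: float               # s
    end: float                 # s

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class CalibrationPair:
    """Two-point (current -> mmHg) calibrations before and after a session.

    Each anchor set is ((current_zero, mmhg_zero), (current_air, mmhg_air)),
    conventionally the zero-oxygen and air-saturated points.
    """

    pre: tuple[tuple[float, float], tuple[float, float]]
    post: tuple[tuple[float, float], tuple[float, float]]
    session_duration: float    # hours

    def __post_init__(self) -> None:
        for anchors in (self.pre, self.post):
            (c0, _), (c1, _) = anchors
            if c0 == c1:
                raise ValueError("degenerate calibration anchors (zero span)")


# --------------------------------------------------------------------------
# filtering / resampling helpers


def _sosfiltfilt(trace: SignalTrace, sos: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, trace.values)


def resample_trace(trace: SignalTrace, fs_out: float) -> SignalTrace:
    """Polyphase anti-aliased resampling to ``fs_out``."""
    if fs_out == trace.sampling_rate:
        return trace
    frac = Fraction(fs_out / trace.sampling_rate).limit_denominator(1000)
    out = signal.resample_poly(trace.values, frac.numerator, frac.denominator,
                               padtype="line")
    return trace.with_values(out, sampling_rate=fs_out)


def lowpass_velocity(velocity: SignalTrace, cutoff: float = 10.0,
                     order: int = 5) -> SignalTrace:
    sos = signal.butter(order, cutoff, btype="low",
                        fs=velocity.sampling_rate, output="sos")
    return velocity.with_values(_sosfiltfilt(velocity, sos))


# --------------------------------------------------------------------------
# behavior


def binarize_locomotion(accel: SignalTrace,
                        a_c: float = ACCEL_THRESHOLD) -> BehaviorMask:
    """Flag locomotion where |acceleration| >= a_c (threshold inclusive).

    ``accel`` should be the first derivative of the 10-Hz low-passed
    velocity (see :func:`lowpass_velocity`).
    """
    flags = (np.abs(accel.values) >= a_c).astype(int)
    return BehaviorMask(flags, accel.sampling_rate, a_c)


def segment_rest(mask: BehaviorMask, min_gap: float = REST_MIN_GAP,
                 min_len: float = REST_MIN_LEN) -> list[RestSegment]:
    """Maximal quiet segments >= ``min_len`` s, starting >= ``min_gap`` s
    after the previous locomotion sample.

    The trace start counts as a locomotion offset (a guard of ``min_gap``
    applies there too); segments are clipped to the trace end.
    """
    fs = mask.sampling_rate
    n = len(mask)
    loco = np.flatnonzero(mask.flags == 1)
    # quiet run boundaries in samples: starts after each locomotion sample
    boundaries = np.concatenate([[-1], loco, [n]])
    segments: list[RestSegment] = []
    for prev_end, nxt in zip(boundaries[:-1], boundaries[1:]):
        if nxt - prev_end <= 1:
            continue
        start = (prev_end + 1) / fs + min_gap
        end = nxt / fs
        if end - start >= min_len:
            segments.append(RestSegment(start, end))
    # keep maximal runs only: consecutive loco samples produce no candidates,
    # and candidates are naturally ordered and non-overlapping
    return segments


# --------------------------------------------------------------------------
# oxygen


def preprocess_oxygen(raw: SignalTrace, cutoff: float = 1.0,
                      fs_out: float = 30.0, order: int = 5) -> SignalTrace:
    """1-Hz fifth-order Butterworth low-pass, then resample to 30 Hz."""
    if raw.sampling_rate < 60.0:
        raise ValueError(
            f"oxygen preprocessing requires >= 60 Hz input, got "
            f"{raw.sampling_rate} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=raw.sampling_rate,
                        output="sos")
    filt = raw.with_values(_sosfiltfilt(raw, sos))
    return resample_trace(filt, fs_out)


def correct_drift(raw: SignalTrace, cal: CalibrationPair) -> SignalTrace:
    """Time-varying two-point calibration: electrode current -> mmHg.

    The sample at t maps through the linear calibration interpolated between
    the pre-session anchors (at trace start) and post-session anchors (at
    trace end), removing slow electrode sensitivity drift.
    """
    (c0a, p0a), (c1a, p1a) = cal.pre
    (c0b, p0b), (c1b, p1b) = cal.post
    gain_pre = (p1a - p0a) / (c1a - c0a)
    gain_post = (p1b - p0b) / (c1b - c0b)
    off_pre = p0a - gain_pre * c0a
    off_post = p0b - gain_post * c0b
    w = np.linspace(0.0, 1.0, raw.n)
    gain = (1 - w) * gain_pre + w * gain_post
    offset = (1 - w) * off_pre + w * off_post
    return raw.with_values(gain * raw.values + offset, units="mmHg")


# --------------------------------------------------------------------------
# electrophysiology


def filter_lfp_mua(raw: SignalTrace, lfp_band: tuple[float, float] = (0.1, 300.0),
                   mua_band: tuple[float, float] = (300.0, 3000.0),
                   order: int = 5) -> tuple[SignalTrace, SignalTrace]:
    """Split a broadband record into LFP and MUA by zero-phase band-passes."""
    if raw.sampling_rate < 10_000.0:
        raise ValueError(
            f"LFP/MUA split requires >= 10 kHz input, got "
            f"{raw.sampling_rate} Hz")
    out = []
    for band in (lfp_band, mua_band):
        sos = signal.butter(order, band, btype="band",
                            fs=raw.sampling_rate, output="sos")
        out.append(raw.with_values(_sosfiltfilt(raw, sos), units="uV"))
    return out[0], out[1]


def extract_blp(lfp: SignalTrace, band: str, fs_out: float = 20.0,
                env_cutoff: float = 1.0) -> SignalTrace:
    """Band-limited power envelope at 20 Hz.

    Third-order zero-phase Butterworth band-pass, squaring with full-wave
    rectification, <1 Hz third-order low-pass, polyphase resampling to
    20 Hz.  Small negative excursions from the zero-phase low-pass and
    resampling are clipped: power is non-negative by construction.
    """
    if band not in BLP_BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {list(BLP_BANDS)}")
    lo, hi = BLP_BANDS[band]
    sos = signal.butter(3, (lo, hi), btype="band", fs=lfp.sampling_rate,
                        output="sos")
    narrow = _sosfiltfilt(lfp, sos)
    power = np.abs(narrow ** 2)
    sos_lp = signal.butter(3, env_cutoff, btype="low", fs=lfp.sampling_rate,
                           output="sos")
    env = signal.sosfiltfilt(sos_lp, power)
    out = resample_trace(lfp.with_values(env, units="uV^2"), fs_out)
    vals = np.clip(out.values, 0.0, None)
    meta = dict(lfp.meta)
    meta["band"] = band
    return SignalTrace(vals, sampling_rate=fs_out, units="uV^2", t0=lfp.t0,
                       meta=meta)


def _mad_sd(x: np.ndarray) -> float:
    """Robust SD: median absolute deviation x 1.4826 (Gaussian-consistent)."""
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def spike_rate(mua: SignalTrace, threshold_sd: float = 3.0,
               bin_ms: float = 1.0, fwhm_ms: float = 10.0) -> SignalTrace:
    """Threshold-crossing rate from the MUA band.

    Events are upward crossings of ``threshold_sd`` background SDs (robust
    MAD estimate, insensitive to the spikes themselves), counted in 1-ms
    bins and smoothed with a Gaussian kernel of 10-ms FWHM.  Output units
    are events/s on the 1-ms grid.
    """
    x = mua.values
    if x.size == 0:
        raise ValueError("empty trace")
    sd = _mad_sd(x)
    if sd == 0:
        thresh = np.inf           # silent trace: no crossings
    else:
        thresh = threshold_sd * sd
    above = x >= thresh
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    bin_samples = max(int(round(bin_ms * 1e-3 * mua.sampling_rate)), 1)
    n_bins = x.size // bin_samples
    counts = np.bincount(np.minimum(onsets // bin_samples, n_bins - 1),
                         minlength=n_bins)[:n_bins]
    fs_out = mua.sampling_rate / bin_samples
    rate = counts.astype(float) * fs_out      # events per second
    sigma_bins = (fwhm_ms / bin_ms) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4 * sigma_bins))
    t = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (t / sigma_bins) ** 2)
    kern /= kern.sum()
    smooth = signal.fftconvolve(rate, kern, mode="same")
    return SignalTrace(np.clip(smooth, 0.0, None), sampling_rate=fs_out,
                       units="events/s", t0=mua.t0)


# --------------------------------------------------------------------------
# respiration


def respiration_rate(thermo: SignalTrace,
                     ) -> tuple[np.ndarray, SignalTrace | None]:
    """Expiratory peak times and instantaneous breathing rate.

    Peaks are negative-going zero crossings of the first derivative of the
    thermocouple signal (i.e. local maxima).  The rate trace is the
    reciprocal inter-peak interval resampled onto the thermocouple grid by
    previous-interval holding.  With fewer than 2 peaks the rate is
    undefined and ``None`` is returned with a warning.
    """
    x = thermo.values
    dx = np.diff(x)
    down = np.flatnonzero((dx[:-1] > 0) & (dx[1:] <= 0)) + 1
    peak_times = thermo.t0 + down / thermo.sampling_rate
    if down.size < 2:
        warnings.warn("fewer than 2 expiratory peaks: rate undefined",
                      stacklevel=2)
        return peak_times, None
    intervals = np.diff(peak_times)
    inst = 1.0 / intervals
    t = thermo.times
    idx = np.clip(np.searchsorted(peak_times[1:], t, side="right"),
                  0, inst.size - 1)
    rate_vals = inst[idx]
    rate = SignalTrace(rate_vals, sampling_rate=thermo.sampling_rate,
                       units="Hz", t0=thermo.t0)
    return peak_times, rate
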