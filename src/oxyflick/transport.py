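"""From RBC trains to capillary and tissue oxygen tension.

Each passing RBC is a point-like oxygen source: at a fixed point on the
capillary wall the oxygen tension peaks at the RBC value as the cell passes
and relaxes toward the inter-RBC (plasma) value between cells — the
erythrocyte-associated transient (EAT), modeled as a two-sided exponential
of amplitude ``po2_rbc - po2_plasma`` (80 - 28 = 52 mmHg for the reference
awake-mouse values) and time constant ``decay_tau``.

The surrounding tissue is a Krogh cylinder: a single capillary of radius R
(3 um) supplying a concentric tissue cylinder of radius R_t (20 um) with
uniform oxygen consumption CMRO2 and diffusion coefficient D_t.  At
steady state the radial profile is

    PtO2(r) = PwO2 + CMRO2/(4 alpha_t D_t) * (r^2 - R^2 - 2 R_t^2 ln(r/R)),

which equals the wall value at r = R and decreases monotonically to a
minimum at the cylinder edge.  Temporal fluctuations of the wall oxygen
reach the tissue low-pass filtered with the diffusive response time
``tau = R_t^2 ln(R_t/R) / (2 D_t)`` (~0.136 s at the defaults), are averaged
over the ~10-um sampling region of a polarographic probe, and finally pass
through the electrode's own smoothing (1-Hz fifth-order Butterworth, then a
30-Hz output grid, matching the experimental preprocessing).

:func:`simulate_ensemble` runs the whole chain over many trains with
spectral exponents drawn uniformly from the experimentally observed
0.6-1.4 range and flow-dependent EAT baselines, then fits the 0.01-1 Hz
power law of each simulated tissue trace — the model counterpart of the
measured tissue-oxygen exponent distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .preprocessing import resample_trace
from .rbc import RBCTrainConfig, generate_train
from .spectral import DEFAULT_BAND, fit_power_law, multitaper_psd
from .trace import RBCTrain, SignalTrace

__all__ = ["EATParams", "KroghParams", "EnsembleSummary", "eat_amplitude",
           "capillary_po2", "krogh_profile", "krogh_drop",
           "tissue_response_time", "tissue_po2", "simulate_ensemble"]


@dataclass(frozen=True)
class EATParams:
    """Erythrocyte-associated transient: RBC and plasma oxygen, decay time."""

    po2_rbc: float = 80.0        # mmHg at the passing RBC
    po2_plasma: float = 28.0     # mmHg in the inter-RBC plasma gap
    decay_tau: float = 0.0112    # s; ~ half the median inter-RBC interval

    def __post_init__(self) -> None:
        if not self.po2_rbc > self.po2_plasma >= 0:
            raise ValueError("need po2_rbc > po2_plasma >= 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")


@dataclass(frozen=True)
class KroghParams:
    """Krogh cylinder constants (defaults: mouse cortex literature values)."""

    D_t: float = 2800.0          # tissue O2 diffusion, um^2/s
    alpha_t: float = 1.39        # O2 solubility, uM/mmHg
    cmro2: float = 3.0           # consumption, umol/cm^3/min
    R_vessel: float = 3.0        # um
    R_tissue: float = 20.0       # um
    PwO2: float = 28.0           # wall oxygen tension, mmHg

    def __post_init__(self) -> None:
        if not (0 < self.R_vessel < self.R_tissue):
            raise ValueError("need 0 < R_vessel < R_tissue")
        if min(self.D_t, self.alpha_t, self.cmro2) <= 0:
            raise ValueError("D_t, alpha_t and cmro2 must be positive")

    @property
    def cmro2_uM_per_s(self) -> float:
        # umol/cm^3/min -> uM/s:  1 umol/cm^3 = 1000 uM; /60 for per second
        return self.cmro2 * 1000.0 / 60.0


@dataclass(frozen=True)
class EnsembleSummary:
    target_betas: np.ndarray
    fitted_betas: np.ndarray
    mean_beta: float
    ci95: tuple[float, float]    # empirical 2.5/97.5 percentiles
    n_trains: int
    n_failed: int
    seed: int


def eat_amplitude(p: EATParams) -> float:
    """EAT magnitude: RBC minus plasma oxygen tension (mmHg)."""
    return p.po2_rbc - p.po2_plasma


def capillary_po2(train: RBCTrain, p: EATParams, fs: float = 250.0,
                  ) -> SignalTrace:
    """Wall oxygen tension: plasma baseline + superposed two-sided EATs.

    Each event contributes ``amplitude * exp(-|t - t_i| / decay_tau)``; the
    superposition is capped at ``po2_rbc`` (an RBC cannot raise the local
    tension above its own).
    """
    if fs < 100.0:
        raise ValueError("capillary grid must be >= 100 Hz")
    t0 = train.event_times[0]
    t = train.event_times - t0
    n = int(np.floor(t[-1] * fs)) + 1
    impulses = np.zeros(n)
    idx = np.clip(np.round(t * fs).astype(int), 0, n - 1)
    np.add.at(impulses, idx, 1.0)
    half = int(np.ceil(8.0 * p.decay_tau * fs))
    lags = np.arange(-half, half + 1) / fs
    kern = eat_amplitude(p) * np.exp(-np.abs(lags) / p.decay_tau)
    vals = p.po2_plasma + signal.fftconvolve(impulses, kern, mode="same")
    vals = np.minimum(vals, p.po2_rbc)
    return SignalTrace(vals, sampling_rate=fs, units="mmHg", t0=t0,
                       meta={"kind": "capillary_po2"})


def krogh_profile(kp: KroghParams, r: float | np.ndarray) -> float | np.ndarray:
    """Steady-state tissue PO2 at radius r (um) from the capillary axis."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < kp.R_vessel) or np.any(r_arr > kp.R_tissue):
        raise ValueError(
            f"r must lie within [{kp.R_vessel}, {kp.R_tissue}] um")
    coef = kp.cmro2_uM_per_s / (4.0 * kp.alpha_t * kp.D_t)   # mmHg / um^2
    bracket = (r_arr ** 2 - kp.R_vessel ** 2
               - 2.0 * kp.R_tissue ** 2 * np.log(r_arr / kp.R_vessel))
    out = kp.PwO2 + coef * bracket
    return float(out) if np.isscalar(r) else out


def krogh_drop(kp: KroghParams, probe_r: float,
               averaging_um: float = 10.0) -> float:
    """Mean radial oxygen drop (<= 0, mmHg) over the probe sampling region.

    The Krogh offset relative to the wall value, averaged with uniform
    weight over radii within ``averaging_um`` of the probe, clipped to the
    cylinder [R_vessel, R_tissue].
    """
    lo = max(probe_r - averaging_um, kp.R_vessel)
    hi = min(probe_r + averaging_um, kp.R_tissue)
    r = np.linspace(lo, hi, 512)
    return float(np.mean(krogh_profile(kp, r) - kp.PwO2))


def tissue_response_time(kp: KroghParams) -> float:
    """Diffusive response time tau = R_t^2 ln(R_t/R) / (2 D_t), seconds."""
    return (kp.R_tissue ** 2 * np.log(kp.R_tissue / kp.R_vessel)
            / (2.0 * kp.D_t))


def _first_order_lowpass(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact discretization of dy/dt = (x - y)/tau, initialized at x[0]."""
    if tau <= 0:
        return x.copy()
    a = 1.0 - np.exp(-dt / tau)
    zi = signal.lfilter_zi([a], [1.0, a - 1.0]) * x[0]
    y, _ = signal.lfilter([a], [1.0, a - 1.0], x, zi=zi)
    return y


def tissue_po2(cap: SignalTrace, kp: KroghParams, probe_r: float = 15.0,
               electrode_cutoff: float = 1.0, fs_out: float = 30.0,
               ) -> SignalTrace:
    """Tissue oxygen at the probe: diffusion smoothing + Krogh offset +
    electrode filtering.

    The capillary-wall trace is low-passed with the first-order diffusive
    response (time constant :func:`tissue_response_time`), offset by the
    mean Krogh radial drop over the 10-um probe sampling region, smoothed by
    the electrode's 1-Hz fifth-order Butterworth response (zero-phase, as in
    the data preprocessing), and resampled to the 30-Hz analysis grid.
    """
    if not kp.R_vessel <= probe_r <= kp.R_tissue:
        raise ValueError(
            f"probe_r must lie within [{kp.R_vessel}, {kp.R_tissue}] um")
    tau = tissue_response_time(kp)
    dt = 1.0 / cap.sampling_rate
    vals = _first_order_lowpass(cap.values, dt, tau)
    vals = vals + krogh_drop(kp, probe_r)
    sos = signal.butter(5, electrode_cutoff, btype="low",
                        fs=cap.sampling_rate, output="sos")
    vals = signal.sosfiltfilt(sos, vals)
    out = SignalTrace(vals, sampling_rate=cap.sampling_rate, units="mmHg",
                      t0=cap.t0, meta={"kind": "tissue_po2",
                                       "probe_r": probe_r})
    return resample_trace(out, fs_out)


# --------------------------------------------------------------------------
# ensemble


def _flow_to_eat(flow_mm_s: float, base: EATParams) -> EATParams:
    """Map capillary flow speed to EAT parameters.

    Plasma oxygen rises linearly from 20 mmHg at 0.3 mm/s to 40 mmHg at
    1.0 mm/s (slower flow -> more complete extraction of the plasma gap ->
    larger EAT), passing through the reference 28 mmHg; the RBC tension is
    held at 80 mmHg.
    """
    v = np.clip(flow_mm_s, 0.3, 1.0)
    plasma = 20.0 + (v - 0.3) / 0.7 * 20.0
    return replace(base, po2_plasma=plasma)


def simulate_ensemble(n_trains: int = 100, duration: float = 2400.0,
                      beta_range: tuple[float, float] = (0.6, 1.4),
                      flow_range: tuple[float, float] = (0.3, 1.0),
                      base_seed: int = 0, fs: float = 250.0,
                      train_cfg: RBCTrainConfig | None = None,
                      eat: EATParams | None = None,
                      krogh: KroghParams | None = None,
                      band: tuple[float, float] = DEFAULT_BAND,
                      probe_r: float = 15.0,
                      max_failure_frac: float = 0.05) -> EnsembleSummary:
    """Distribution of fitted tissue-oxygen power-law exponents over trains.

    Per train: draw a target interval-sequence exponent uniformly from
    ``beta_range`` and a flow speed from ``flow_range``; generate ~duration
    seconds of correlated RBC train; run the EAT -> diffusion -> electrode
    chain; fit the 0.01-1 Hz power law of the tissue trace.  Sub-streams are
    seeded ``base_seed + index`` so the ensemble is reproducible and
    order-invariant.  Trains whose fit fails are excluded (counted); more
    than ``max_failure_frac`` failures aborts.
    """
    if n_trains < 30:
        raise ValueError("need at least 30 trains for a stable summary")
    cfg0 = train_cfg or RBCTrainConfig(duration=duration)
    eat0 = eat or EATParams()
    kp = krogh or KroghParams()
    targets, fitted = [], []
    n_failed = 0
    for i in range(n_trains):
        seed_i = base_seed + i
        rng = np.random.default_rng((seed_i, 0xE17))
        beta_i = rng.uniform(*beta_range)
        flow_i = rng.uniform(*flow_range)
        try:
            cfg = replace(cfg0, target_beta=beta_i, duration=duration)
            train = generate_train(cfg, seed=seed_i * 7919)
            p = _flow_to_eat(flow_i, eat0)
            cap = capillary_po2(train, p, fs=fs)
            tis = tissue_po2(cap, replace(kp, PwO2=p.po2_plasma),
                             probe_r=probe_r)
            fit = fit_power_law(multitaper_psd(tis), band=band)
            targets.append(beta_i)
            fitted.append(fit.beta)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > max_failure_frac * n_trains:
        raise RuntimeError(
            f"{n_failed}/{n_trains} trains failed the transport/fit chain")
    fitted_arr = np.asarray(fitted)
    lo, hi = np.percentile(fitted_arr, [2.5, 97.5])
    return EnsembleSummary(np.asarray(targets), fitted_arr,
                           float(fitted_arr.mean()), (float(lo), float(hi)),
                           len(fitted), n_failed, base_seed)
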