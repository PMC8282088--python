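# Methods

`oxyflick` asks a single scientific question: can the stochastic spacing of
red blood cells (RBCs) in a capillary, with no neural input at all, generate
the 1/f-like fluctuations observed in cortical tissue oxygen? The package
implements both sides of the argument — the scaling estimators that
characterize 1/f-like dynamics, and a generative model from RBC passage
statistics to the electrode-filtered tissue-oxygen signal — together with
the signal-conditioning and neurovascular-coupling analyses needed to show
that neural band-limited power does *not* account for the oxygen
fluctuations.

## Scaling estimators

### Multitaper spectra and the spectral exponent β

Power spectral densities are estimated by averaging eigenspectra over DPSS
(Slepian) tapers. Leakage control matters here: a periodogram's sidelobe
floor flattens steep spectra and biases power-law fits. Defaults are a
whole-record estimate with time-bandwidth `nw = 4` and `k = 7` tapers
(`k = 2·nw − 1`, the classical choice); requesting more tapers than `2nw − 1`
is refused because the higher-order tapers leak badly. Point processes
(RBC trains) are binarized onto a uniform grid (0 = plasma, 1 = RBC,
default 250 Hz) and mean-rate-removed before tapering.

The spectral exponent β of `P(f) ∝ 1/f^β` is fitted by *unweighted*
ordinary least squares of log₁₀P on log₁₀f over 0.01–1 Hz. Because linearly
spaced frequency bins crowd the top decade of a log axis, the spectrum is
first resampled onto bins equally spaced in log f (20 per decade). Within
each bin both frequency and power are averaged in the log domain (geometric
means): this is the reduction consistent with the subsequent log–log
regression, and it keeps an exact power law exactly on its line — the basis
of the machine-precision fit property tested in the suite. Bin-averaging
(never interpolation) guarantees no power is invented; non-positive bins,
which cannot be log-averaged, are dropped and counted. DC and Nyquist are
excluded. β is reported positive for decaying spectra.

### Detrended fluctuation analysis (DFA)

DFA complements the spectral fit in the time domain and tolerates
nonstationarity. The series is demeaned and cumulatively summed; the profile
is cut into non-overlapping windows of n samples (taken from the start,
trailing remainder dropped, single forward pass); each window is detrended
with an order-2 polynomial — chosen so that linear trends in the *raw*
signal, which integrate to quadratics, are removed; F(n) is the RMS of the
residuals over all complete windows. α and its R² come from unweighted OLS
of log F on log n over 16 log-spaced scales from 10 samples to N/4 (the
upper quarter limit keeps at least four windows per scale). For fractional
Gaussian noise α = H and β = 2H − 1, so the two estimators cross-validate on
the same synthetic input; the suite asserts the ladder α(white) = 0.5,
α(∫white) ≈ 1.5, α(fGn H) ≈ H.

A deliberately naive loop-per-window implementation (`dfa_oracle`) is kept
in the package and the optimized vectorized path is required to agree with
it to 1e-10 relative on random inputs.

### Model comparison

Whether a spectrum is better described by a power law, an exponential decay,
or a log-normal shape is decided by small-sample-corrected AIC on the
identical log-resampled point set. Each candidate is a two-coefficient
linear regression of ln P on, respectively, ln f, f, or (ln f)²; with the
residual variance this gives exactly K = 3 parameters per model, making the
AICc values directly comparable. σ̂² is the maximum-likelihood SSE/n, and
AICc = n·ln σ̂² + 2K + 2K(K+1)/(n−K−1). A pair of models within ΔAICc < 2 is
declared indistinguishable. The (ln f)² reading of "log-normal" keeps K = 3;
the full quadratic in ln f (K = 4) is available via
`log_normal_form="quadratic"` for sensitivity analysis.

## Signal conditioning

Tissue oxygen is low-passed at 1 Hz (fifth-order Butterworth) and resampled
to 30 Hz; electrode sensitivity drift is removed by interpolating linearly
in time between pre- and post-session two-point calibrations. Broadband
extracellular voltage splits into LFP (0.1–300 Hz) and MUA (300–3000 Hz)
by fifth-order band-passes. Band-limited power (sub-alpha 1–8 Hz, beta
10–30 Hz, gamma 40–100 Hz) is third-order band-pass → squaring/full-wave
rectification → <1 Hz low-pass → 20 Hz. Spike rate counts 3-SD threshold
crossings in 1-ms bins smoothed by a 10-ms-FWHM Gaussian; the "background"
SD is the MAD × 1.4826 over the whole trace, robust to the spikes
themselves. Locomotion is flagged where |acceleration| ≥ 3 cm/s² (inclusive
threshold, matching the Heaviside convention H(0) = 1) on 10-Hz-low-passed
velocity; rest segments are quiet runs of ≥ 60 s beginning ≥ 4 s after the
last locomotion sample, with the trace start treated as a locomotion offset
and segments clipped to the record.

All Butterworth filters run forward–backward (zero phase). The analyses
downstream are spectra, envelopes and scaling exponents — all
phase-agnostic — and symmetric application preserves event timing; the cost
is a doubled effective order, which is accepted uniformly. Resampling is
polyphase with anti-aliasing and line-extension padding.

## Neurovascular coupling (HRF)

The mapping from gamma-band LFP power to tissue oxygen is treated as a
linear time-invariant system. The impulse response solves the least-squares
problem with the Toeplitz convolution design built from the raw (not
z-scored) band-power regressor — the kernel then carries the units mmHg per
unit power. The solve uses a stable least-squares routine rather than
explicit normal equations, and spans only the rows for which oxygen was
actually observed: the trailing rows of the padded design describe
post-record decay that was never measured, and forcing them to zero would
bias the kernel (the noiseless round-trip test would fail by orders of
magnitude). Kernel support defaults to 15 s at 20 Hz.

The kernel is smoothed with a Savitzky–Golay filter (order 3, 11 points;
cubic-preserving) and parameterized by two gamma-variate lobes
`A·(t/T)^α·e^{α(1−t/T)}` with α = (T/W)²·8 ln 2, fitted by best-of-20
Nelder–Mead restarts with seeded jittered starts and log-parameterized
positive T, W. In this form each lobe peaks at exactly t = T with value A
and has FWHM ≈ W, so the reported numbers are directly the amplitude,
time-to-peak and width.

Predictive power is always out-of-sample: the kernel from the first half of
a session is convolved with the second half's regressor, and R² is the
squared correlation with the observed second half after discarding the first
kernel-length of the test half (the convolution warm-up responds to unseen
first-half input). Train/test index spans are recorded and asserted
disjoint.

## The RBC-spacing model

### Trains

Inter-RBC intervals are drawn i.i.d. from a two-component mixture:

* a truncated normal with location 22.4 ms and scale IQR/1.349 = 22.8 ms
  (awake-mouse resting statistics, median ± IQR = 22.4 ± 30.7 ms), left-
  truncated at 10 ms — an ~7 μm erythrocyte at 0.3–1 mm/s cannot pass
  faster;
* with probability 0.5%, a stall: a lognormal matched to median 1.65 s and
  IQR 1.32 s, floored at the 1-s stall definition.

Serial correlation is then imposed by a one-shot rank remap: a Gaussian
surrogate sequence with 1/f^β amplitude spectrum and uniform random phases
is synthesized by inverse FFT, and the sampled intervals are reordered onto
the surrogate's ranks. The output is an exact permutation of the input — the
marginal is untouched, a property the suite asserts as multiset equality —
while the spectral exponent is imposed approximately. Stalls participate in
the remap like any value, landing on the surrogate's largest excursions;
this clusters them, consistent with the positive lag-1 Poincaré correlation
of real capillaries. An iterative (amplitude-readjusting) remap was
evaluated and rejected: with the heavy-tailed stall component it neither
stabilizes the binarized-train exponent nor preserves the stall clustering
that drives the ensemble behavior.

Recovery: on stall-free trains the binarized-train exponent recovers the
target within ~0.05 across 0.6–1.4. With stalls included the recovery is
strongly asymmetric — see "known limitations" below.

### Transport chain

Each RBC is a point-like oxygen source. At a fixed point on the capillary
wall, oxygen tension is the plasma baseline plus a two-sided exponential
erythrocyte-associated transient (EAT) per event, amplitude
`po2_rbc − po2_plasma` (80 − 28 = 52 mmHg at the reference values) and time
constant 11.2 ms (half the median inter-RBC interval: the transient should
decay between typical passages but overlap within bursts; exposed in
`EATParams`). Superposition is additive, capped at the RBC tension — a cell
cannot raise the local tension above its own.

The tissue is a Krogh cylinder (vessel radius 3 μm, tissue radius 20 μm,
D_t = 2800 μm²/s, α_t = 1.39 μM/mmHg, CMRO2 = 3 μmol·cm⁻³·min⁻¹, converted
internally to 50 μM/s). The steady radial profile
`PwO2 + CMRO2/(4α_tD_t)·(r² − R² − 2R_t²·ln(r/R))` equals the wall value at
r = R and drops 3.62 mmHg at the cylinder edge with the defaults. Temporal
fluctuations reach the tissue through a first-order low-pass with the
diffusive response time τ = R_t²·ln(R_t/R)/(2D_t) ≈ 0.136 s. The probe
signal is offset by the Krogh drop averaged uniformly over radii within
10 μm of the probe (clipped to the cylinder), then passed through the same
1-Hz fifth-order Butterworth + 30-Hz resampling used for experimental
oxygen records — the electrode and its acquisition chain do not distinguish
simulated from measured tension.

### Ensemble

`simulate_ensemble` draws, per train, a target interval-sequence exponent
uniform on [0.6, 1.4] (the experimentally observed range) and a flow speed
uniform on [0.3, 1.0] mm/s; flow maps linearly to the plasma baseline,
20 mmHg at the slowest flow (near-complete extraction of the plasma gap) to
40 mmHg at the fastest, passing through the reference 28 mmHg — so slower
flow means larger EATs. Each train runs the full chain and its tissue trace
is fitted for β over 0.01–1 Hz; the summary is the mean and the empirical
2.5th/97.5th percentiles. Sub-streams are seeded `base_seed + index`, making
the ensemble reproducible and order-invariant.

Problem sizes: the package's reference run uses 200 trains of 2400 s (the
full session duration the model emulates) at a 250-Hz transport grid —
about one minute of compute — versus 1,000 trains in the full study design;
at 200 trains the percentile endpoints are stable to ~0.01 across seeds.

## What the synthetic data do and do not emulate

The generators reproduce the *statistical structure* the analyses consume:
marginal and serial interval statistics of capillary trains, exact-covariance
fGn (circulant embedding — the draw has exactly the target autocovariance,
not an approximation), band-limited envelopes, known HRF convolutions, known
locomotion bouts and expiratory peaks. They do not emulate electrode drift
artifacts, imaging noise, respiration–locomotion cross-coupling, or any
capillary-network interaction (each train is one capillary in isolation).
Passing tests therefore demonstrate estimator and model correctness under
controlled ground truth, not robustness to every artifact of real records.

## Numerical choices and degenerate inputs

* Circulant embedding pads to the next power of two; a negative embedding
  eigenvalue beyond roundoff raises rather than being clipped silently.
* Constant inputs: DFA refuses (F ≡ 0, α undefined); Poincaré correlation
  reports NaN; a constant HRF regressor is a rank-deficient design and the
  deconvolution refuses rather than regularizing.
* A flat spectrum has roundoff-level log-power variance; the power-law fit
  reports R² = 1 there instead of a 0/0 artifact.
* Two RBC events falling in one binarization bin collapse to a single 1 and
  are counted and warned about.
* Zero-coherence significance uses the standard `1 − 0.05^(1/(K−1))` level
  for K taper×segment averages.
* Ensemble trains whose fit fails are excluded and counted; more than 5%
  failures aborts the ensemble.

## Known limitations

* With the 0.5% per-interval stall mixture, stalls occupy a sizeable
  fraction of simulated time and their shot-like low-frequency power sets a
  floor of ~1.1 on the fitted tissue exponent: ensembles compress the low
  tail of the input exponent range. The mean and upper percentile of the
  ensemble reproduce the model-reported values; the lower percentile sits
  above the reported 0.93 by ~0.17. Reducing stall prevalence to a
  time-fraction reading (~1e-4 per interval) removes the floor, but the
  package keeps the per-interval reading as configured.
* The imposed exponent is approximate under rank remapping; only stall-free
  trains recover it tightly.
* DFA uses a single forward pass (no reversed-pass averaging) and drops the
  trailing partial window.
* The gamma-variate fit is a nonconvex optimization; with pathological
  kernels the best-of-restarts simplex can converge to a local minimum
  (`converged` is reported).
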