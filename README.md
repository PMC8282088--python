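# oxyflick

Cortical tissue oxygen, recorded polarographically in awake mice, fluctuates
with a 1/f-like power spectrum (`P(f) ∝ 1/f^β`, β ≈ 1–2 over 0.01–1 Hz) that
is only weakly coupled to local neural activity. `oxyflick` implements the
computational machinery to study a non-neuronal explanation: red blood cells
pass through a capillary in single file with stochastic, serially correlated
spacing (including rare >1 s "stalls"), each cell carrying an
erythrocyte-associated oxygen transient (EAT); diffusion into the
surrounding tissue low-pass filters this pulse train, and the result is a
1/f-like tissue-oxygen signal with no neural input at all.

The package is aimed at researchers in neurovascular physiology and
hemodynamic signal analysis. It provides:

* **Scaling estimators** — multitaper (DPSS) spectra for continuous traces
  and point processes; spectral-exponent fits by unweighted OLS of log P on
  log f over 0.01–1 Hz after log-uniform resampling; detrended fluctuation
  analysis (order-2 detrending, `F(n) ∝ n^α`), with an independent naive
  implementation for cross-checking. For fractional Gaussian noise the two
  satisfy α = H and β = 2H − 1.
* **Model comparison** — AICc (`AIC = n ln σ̂² + 2K`, K = 3 per model) of
  power-law vs exponential vs log-normal spectral shapes, with the ΔAICc < 2
  indistinguishability rule.
* **Neurovascular coupling** — hemodynamic response function (HRF)
  deconvolution `H = (LᵀL)⁻¹LᵀV` from gamma-band LFP power via the Toeplitz
  convolution design, Savitzky–Golay smoothing, two-gamma-variate
  parameterization (amplitude, time-to-peak, FWHM), and strictly
  out-of-sample split-half prediction R².
* **The RBC-spacing model** — interval sampling from a truncated-normal +
  stall mixture, long-range correlation by rank-remapping onto a 1/f^β
  Fourier surrogate (marginal preserved exactly), EAT superposition, Krogh
  cylinder radial profile and diffusive response time, probe averaging and
  electrode filtering, and the ensemble over trains with exponents drawn
  from the experimentally observed 0.6–1.4 range.
* **Synthetic ground truth** — circulant-embedding fGn (exact covariance),
  white/periodic/hybrid traces, behavior sessions with known locomotion
  bouts, respiration with known expiratory peaks, and coupled
  band-power/oxygen sessions with a known kernel; plus the preprocessing
  chain (filtering, BLP extraction, spike rate, rest segmentation,
  calibration-drift correction) these analyses assume.

Analysis methods are sklearn-style estimators (`DFAEstimator`,
`PowerLawEstimator`, `SpectrumModelSelector`, `HRFRegressor`) with plain
functional wrappers; simulators are functions over typed configs.

## Worked example

```python
from oxyflick import datasets, run_dfa, fit_power_law, multitaper_psd
from oxyflick.rbc import RBCTrainConfig, generate_train, detect_stalls
from oxyflick.spectral import pointprocess_psd
from oxyflick.transport import EATParams, KroghParams, capillary_po2, tissue_po2

# 1) estimator calibration on exact-covariance fGn with H = 0.9
fgn = datasets.make_fgn(2**17, 30.0, hurst=0.9, seed=2)
beta = fit_power_law(multitaper_psd(fgn)).beta     # expect 2H-1 = 0.8
alpha = run_dfa(fgn).alpha                         # expect H = 0.9

# 2) a 20-minute correlated capillary RBC train with 0.5% stalls
cfg = RBCTrainConfig(target_beta=1.0, duration=1200.0)
train = generate_train(cfg, seed=5)
fit = fit_power_law(pointprocess_psd(train))

# 3) transport chain: EATs -> Krogh cylinder -> electrode
cap = capillary_po2(train, EATParams())            # wall PO2, 28-80 mmHg
tissue = tissue_po2(cap, KroghParams())            # probe signal at 30 Hz
```

Output:

```
fGn H=0.9:  spectral beta = 0.781   DFA alpha = 0.904
RBC train:  26427 events, 116 stalls, binarized-train beta = 1.204
tissue O2:  mean = 48.8 mmHg, fitted beta = 1.394
```

The estimators recover the fGn ground truth (β ≈ 0.8, α ≈ 0.9); the
simulated train's binarized spectrum is 1/f-like; and the transport chain
steepens the in-band slope further — purely from RBC spacing statistics,
the tissue signal lands in the β range reported for real cortical oxygen
recordings.

A command-line interface mirrors the stages
(`oxyflick simulate|preprocess|spectrum|fit-powerlaw|dfa|hrf|compare-models|simulate-train|simulate-ensemble|run`);
`oxyflick run` executes a configured simulate → analyze → report pipeline
and prints summary tables per signal class.

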