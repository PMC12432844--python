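# audiencesync

Inter-brain synchrony analysis for naturalistic group EEG — the kind of
data collected when a whole audience wears mobile EEG while watching a
live performance. The package implements the full analysis chain as a
tested, reusable library:

- **Synthetic audience generator** with known ground truth (shared
  band-limited source modulated by a slow "engagement" gain, spatially
  correlated noise, sparse artifacts, device clock offsets, photoresistor
  blackout traces, 1 Hz performance features with a planted lagged
  influence, respiration traces), so every downstream stage is testable
  without any external recording.
- **Preprocessing**: zero-phase 5th-order Butterworth band-pass (delta
  1–4, theta 4–8, alpha 8–12, beta 12–20 Hz), outlier zeroing at 4 channel
  SDs with 40 ms padding, common average reference, polyphase resampling,
  respiration cleaning (moving-median de-spiking + Savitzky–Golay).
- **Device alignment** from photoresistor blackout onsets (two-segment
  least-squares slope-change detection, shift to the most central onset,
  trim to the common span).
- **Correlated-components ISC**: channel weight vectors maximising the
  ratio of between- to within-subject covariance, time-resolved ISC in
  5 s windows with 80 % overlap, explained-covariance percentages, forward
  models (topographies).
- **Surrogate statistics**: circular-shift nulls, per-window percentile
  thresholds, cluster-based multiple-comparison correction across time and
  neighbouring bands, resting-state baseline tests (Wilcoxon + BH-FDR).
- **Performance features** at a common 1 Hz clock: audio RMS energy, an
  autocorrelation pulse-clarity index, dancer wrist acceleration, dancer
  distance, stage luminance, windowed continuous ratings, and respiration
  synchrony through the same ISC machinery.
- **Granger coupling**: ADF stationarity screening (with automatic
  differencing), pairwise nested-autoregression F-tests over lags 1–15 s,
  BH-FDR over the whole predictor × lag grid.
- **Phase-locking value and band power**: analytic-signal phase, windowed
  PLV for every subject pair and electrode, Welch band power (1 s Hann
  segments, 20 % overlap), 4-SD power outlier filtering.

## The statistics at the core

For subjects k = 1..N with channel data x_k(t), the component weights v
solve the generalized eigenproblem

    Rb v = μ (Rw + λ (tr Rw / D) I) v,
    Rw = Σ_k R_kk,   Rb = Σ_{k≠l} R_kl,

with R_kl the channel cross-covariance between subjects k and l, and the
inter-subject correlation of component i is normalised as

    ISC_i = v_iᵀ Rb v_i / ((N−1) v_iᵀ Rw v_i),

so N identical subjects give ISC = 1. The phase-locking value between
subjects j and k over a window of T samples is

    PLV_jk = | (1/T) Σ_t exp(i(θ_j(t) − θ_k(t))) |  ∈ [0, 1],

with θ the angle of the analytic (Hilbert) signal of band-passed data.
Significance of the ISC time course is assessed against circular-shift
surrogates with cluster-size correction.

## Worked example

```python
import numpy as np
from audiencesync import (SimConfig, WindowGrid, simulate_audience,
                          pooled_covariances, fit_cca, isc_timecourse,
                          explained_covariance, null_isc_distribution,
                          significant_clusters)
from audiencesync.preprocess import bandpass_filter, zero_outliers
from audiencesync.containers import band

cfg = SimConfig(n_subjects=10, n_channels=8, sample_rate=250.0,
                duration=300.0, snr=0.1, seed=42)
group, truth = simulate_audience(cfg)
group = group.map(lambda r: zero_outliers(bandpass_filter(r, band("delta")))[0])

Rw, Rb = pooled_covariances(group)
model = fit_cca(Rw, Rb, group.n_subjects)
print("component ISCs:", np.round(model.isc[:3], 4))
print("explained covariance (%):", np.round(explained_covariance(model)[:3], 2))

series = isc_timecourse(group, model, WindowGrid(), band="delta")[0]
null = null_isc_distribution(group, iterations=200, seed=7, band="delta")
clusters = significant_clusters(series, null)
print("windows above the surrogate 95th percentile:",
      int(np.nansum(series.values > null.percentile_curve())))
print("significant clusters:", len(clusters.significant_clusters))
```

Output:

```
component ISCs: [0.136  0.0148 0.0114]
explained covariance (%): [80.43  8.78  6.71]
windows above the surrogate 95th percentile: 185
significant clusters: 3
```

The first correlated component picks up the shared delta-band source
(ISC₁ = 0.136, far above the remaining components and carrying 80 % of
the positive group covariance); 185 of 296 five-second windows exceed the
per-window 95th percentile of 200 circular-shift surrogates, and the
cluster correction retains 3 clusters of supra-threshold windows, the
signature of genuinely time-locked audience synchrony. With `snr=0` the
same pipeline stays inside the surrogate band for ≈95 % of windows and
returns no significant clusters.

A thin CLI covers the common entry points:

```
audience-sync sim --config sim.yaml --out bundle/ --seed 1
audience-sync run --out results/ --seed 1
```

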