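# Methods

This note documents the models, conventions and numerical choices behind
`audiencesync`, and what the synthetic generator does and does not emulate.

## Signal model of the synthetic audience

Each subject k's channels-by-time record is

    x_k(t) = g(t) · snr · m_k · s(t) + σ_n · n_k(t) + artifacts,

with

- **s(t)** — shared latent source: white noise band-passed with the same
  zero-phase 5th-order Butterworth used in preprocessing (so its spectrum
  matches the analysis band exactly), normalised to unit variance.
- **g(t)** — "engagement" gain in [0, 1], shared by all subjects. Default:
  a random walk at 1 Hz smoothed to a 180 s correlation length and
  min-max rescaled, emulating the few-minute section structure of a staged
  performance. Constant, array-valued and callable profiles are accepted.
- **m_k** — unit-norm scalp projection: a shared random template plus a
  small per-subject jitter (`mixing_jitter`, default 0.1), re-normalised.
  Fully independent per-subject projections would make the group share no
  consistent channel pattern and the correlated-component weights would be
  ill-defined; a shared-template-with-jitter map is the minimal model of a
  common cortical source seen through individually varying anatomy.
- **n_k(t)** — spatially correlated noise with unit channel variance and
  uniform inter-channel correlation 0.3 (covariance (1−ρ)I + ρJ applied
  via its symmetric square root), a coarse stand-in for volume conduction.
- **artifacts** — 200 ms boxcar bursts at `artifact_scale` (default 8)
  channel SDs on a random ~25 % channel subset, Poisson-arriving at
  `artifact_rate` (default 2/min). They exist to exercise the 4-SD outlier
  zeroing stage.

`snr` is a broadband amplitude ratio (shared source vs unit-variance
noise). Note that band-pass filtering concentrates the comparison: after
delta-band filtering the in-band signal-to-noise ratio is roughly 40×
larger than `snr²` at 250 Hz, so even `snr = 0.1` yields a clearly
detectable ISC. Device clock offsets shift each subject's content and the
blackout position in its photoresistor trace consistently, so alignment
can be verified against ground truth.

All randomness derives from one integer seed through fixed sub-stream
indices (source/gain/mixing/noise/artifacts/features/photoresistor/
respiration); outputs are bit-identical across runs for a fixed config.

What the generator does **not** emulate: biophysical head geometry and
realistic topographies, 1/f background spectra, eye/muscle artifact
morphology, non-stationary noise, clock drift (only constant offsets), or
real acoustic waveforms (audio features are simulated directly as series).
Passing tests therefore demonstrate correctness and calibration of the
*statistics*, not robustness to every pathology of mobile EEG.

## Preprocessing conventions

- Band edges: delta 1–4, theta 4–8, alpha 8–12, beta 12–20 Hz; 5th-order
  Butterworth applied forward-backward (zero phase; effective order
  doubling accepted) because ISC and PLV are phase-sensitive.
- Outlier zeroing runs **after** band-passing, so zeroed segments are not
  smeared through the filter; both orders can be composed manually.
  Detection statistics are the per-channel mean and SD over currently
  unmasked samples of the full recording; flagged samples plus 40 ms on
  each side are set to zero and recorded in a boolean mask that propagates
  to every windowed statistic. Strict idempotence is not guaranteed —
  removing a large spike shrinks the SD slightly, so a second pass may
  flag a handful of borderline samples — but the flagged fraction on clean
  simulated data stays well below 1 %.
- Resampling is polyphase with anti-aliasing; upsampling is refused
  (nothing in the pipeline needs it). Respiration cleaning uses a 0.5 s
  moving-median corridor (replacement by interpolation across the flagged
  run) and a 1 s Savitzky–Golay smoother of polynomial order 3 (the order
  is a convention; the sources describing the procedure leave it open).

## Device alignment

The photoresistor blackout onset is found by scanning two-segment
least-squares fits over every candidate breakpoint (O(n) via prefix sums)
and accepting breakpoints whose residual reduction relative to a single
line exceeds 20 %. Because a blackout is plateau → ramp → floor, the
global optimum can sit mid-ramp; the estimate is therefore refined by
re-fitting on the data up to just past the current breakpoint, which
walks it back to the earliest slope change. A slope change is a *kink*,
not a jump, so localisation carries a few samples of spread under sensor
noise; what matters for alignment is that the spread is common across
devices. Recordings are shifted toward the onset minimising the summed
absolute difference to the others and trimmed to the jointly observed
span (no zero-padding, so windowed statistics only ever see co-observed
time). Shifts beyond 10 % of the recording duration raise an error.

## Correlated components and time-resolved ISC

Pooled covariances use pairwise exclusion of masked samples with
pair-specific means. The fit solves `Rb v = μ (Rw + λ(tr Rw/D) I) v`;
shrinkage defaults to λ = 0.1 because 5 s windows of 32-channel data are
rank-deficient without it. ISC values are always computed from the *raw*
covariances, `ISC_i = v_iᵀ Rb v_i / ((N−1) v_iᵀ Rw v_i)`, so that N
identical subjects give exactly 1. Component signs are fixed by making
the largest-magnitude weight positive; forward models are
`A = Rw W (Wᵀ Rw W)⁻¹`.

The time course applies the full-recording weights to window-local
covariances (5 s windows, 1 s hop, half-open at sample resolution, window
timestamp = window start). Per-window refitting was rejected as unstable
at this window length. Since the weights are fixed, each subject is
projected to a scalar series first and all window statistics are
assembled from cumulative sums — mathematically identical to the matrix
form but fast enough to repeat a thousand times for surrogates. Windows
where any subject has less than 50 % unmasked samples are reported as
missing rather than biased. The explained-covariance percentage is the
declared convention `100·max(ISC_i,0)/Σ_j max(ISC_j,0)` over the full
component set.

## Surrogates, clusters and the resting-state baseline

Each surrogate iteration rotates every subject's full record by an
independent uniform offset in [30 s, duration−30 s] (offsets below 30 s
would leak true synchrony) and re-runs the complete fit + time course.
Supra-threshold windows (true ISC₁ above the per-window 95th percentile
of the draws) are clustered by adjacency in time **and** between
neighbouring bands (4-connectivity on the bands × windows grid, with
bands ordered delta–theta–alpha–beta); cluster mass is the count of
windows. The null cluster distribution takes the largest cluster of each
iteration's own exceedances against the same percentile curve; a true
cluster is significant iff its size exceeds the 95th percentile of those
maxima. The resting-state baseline tiles the RS record end-to-end with no
taper (seam windows kept), runs the identical pipeline, and compares each
150 s performance segment to the matching RS windows with a paired
Wilcoxon signed-rank test (exact null below 25 pairs, normal
approximation with continuity correction otherwise), BH-FDR across
segments, pairing by window index within segment.

## Features and the Granger scan

All features land on one 1 Hz grid (linear interpolation onto a 10 Hz
grid, then block-averaging per second). Pulse clarity is a deliberately
simple autocorrelation beat-strength index (onset-envelope
autocorrelation over the 40–200 bpm lag range, peak normalised by lag 0)
— parity with any specific music-information-retrieval toolbox is a
non-goal. Acceleration is the root-summed-square per wrist on a uniform
20 Hz clock, combined as the median across performers (median of two
equals their mean; median is kept for generality). Each feature's
spectral centroid is reported so users can check where its power lies
relative to the EEG band of interest; no threshold is asserted.

The Granger scan screens each predictor with a constant-only ADF test
(AIC lag selection up to ⌊12(n/100)^0.25⌋) and first-differences
non-stationary predictors. For each lag p in 1..15 the SSR-based F-test
compares outcome-on-own-lags against the model augmented with the
predictor's p lags, with (p, n−2p−1) degrees of freedom; each lag is
reported separately (no information-criterion selection), and BH-FDR runs
over the whole predictor × lag family per outcome. The scan is univariate
by design: features may act at different timescales, and a multivariate
model would force a single lag structure. A caution established while
validating the generator: the *minimal* significant lag only identifies
the planted lag when the driving feature is temporally white — an
autocorrelated driver leaks into shorter lags through its own memory.
`simulate_coupled_series` therefore uses white predictors by default,
while the slow gain-coupled feature from `simulate_features` demonstrates
detection but not exact lag attribution.

## PLV and band power

The phase-locking statistic takes the modulus of the mean unit phasor of
the phase difference (without the modulus the quantity would be complex
and could not lie in the stated [0, 1] range). Default windows are 5 s
with 4 s overlap; a non-overlapping switch reproduces 36 back-to-back
windows per 3 minutes. Analysis electrodes default to the central
(C3/C4/Cz) and occipital (O1/Oz/O2) sets. Welch band power uses 250-sample
(1 s at 250 Hz) Hann segments with 50-sample (20 %) overlap, averaged
across channels and then across band bins; per-subject powers beyond 4 SD
of the group mean are dropped. Windowed PLV rows are exported raw — any
averaging per pair is left to downstream modelling, which is out of
scope here.

## Calibration and test scales

The statistical acceptance checks run at reduced scale; the properties
under test are scale-free:

- Null-band coverage: 8 subjects × 8 channels, 10 min at 250 Hz, snr 0,
  200 surrogate iterations.
- Pointwise exceedance calibration (5 % ± 1.5 %): two independent
  6-subject × 4-channel null datasets of 1500 s at 100 Hz (~3000 windows
  pooled); pooling two datasets halves the variance the 80 % window
  overlap induces on the exceedance fraction.
- Cluster family-wise error: 200 replicates of 150 s artifact-free null
  data (6 × 4 at 100 Hz), 200 surrogate iterations each, single band.
- Granger recovery: 100 replicates of n = 600 series at 1 Hz, 6-predictor
  × 15-lag grid, for planted lag 3 at β = 1 and for β = 0.
- Monotonicity: snr grid {0, 0.5, 1, 2} for ISC and von Mises
  concentration grid {0, 1, 2, 4} for PLV, 10 replicates per level.

## Known limitations

- ICA-based artifact rejection, mixed-effects modelling of PLV/power, and
  questionnaire statistics are out of scope; the package exports
  analysis-ready tables instead.
- EDF export is not provided; group recordings travel in a single HDF5
  container (plus tidy CSV for everything windowed).
- The change-point detector assumes a piecewise-linear photoresistor
  response; exotic lighting transitions (slow fades) would need a
  different model.
- Clock drift within a recording is not corrected — only constant
  offsets.
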