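"""Synthetic audience generator with known ground truth.

Emulates the study geometry — an audience of ~20 subjects wearing 32-channel
EEG at 250 Hz for tens of minutes — so every downstream stage (filtering,
outlier zeroing, alignment, ISC, surrogates, Granger coupling) is testable
without any external recording. Each subject's data is

    x_k(t) = gain(t) * snr * m_k * s(t) + noise_scale * n_k(t) + artifacts,

where s(t) is a shared band-limited source, gain(t) a slow "engagement"
envelope in [0, 1], m_k a unit-norm per-subject scalp projection, and
n_k(t) spatially correlated noise with unit channel variance. Device clock
offsets and a photoresistor blackout step exercise the alignment stage;
1 Hz feature series with a planted lagged influence on the gain exercise
the Granger stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .containers import BandSpec, FeatureSeries, GroupRecording, Recording, band
from .preprocess import _bandpass_array

__all__ = ["SimConfig", "GroundTruth", "simulate_audience",
           "simulate_features", "simulate_photoresistor",
           "simulate_respiration", "simulate_coupled_series",
           "CHANNEL_LABELS_32"]

CHANNEL_LABELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "CP5", "CP1", "CP2", "CP6", "P7", "P3",
    "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10", "AFz", "FCz",
]

# fixed sub-stream indices derived from the single global seed
_STREAMS = {"source": 0, "gain": 1, "mixing": 2, "noise": 3, "artifacts": 4,
            "features": 5, "photoresistor": 6, "respiration": 7}


@dataclass
class SimConfig:
    """Study conditions for the synthetic audience.

    Defaults follow the emulated recording setup: 20 subjects, 32 channels,
    250 Hz, 10 minutes, a delta-band shared source, engagement gain with
    ~3-minute sections, sparse large artifacts, and a 3 s feature-to-gain
    coupling.
    """

    n_subjects: int = 20
    n_channels: int = 32
    sample_rate: float = 250.0
    duration: float = 600.0
    band: BandSpec = field(default_factory=lambda: band("delta"))
    snr: float = 1.0
    gain_profile: str | Callable[[np.ndarray], np.ndarray] | np.ndarray = "random_walk"
    gain_corr: float = 180.0          # s, correlation length of the gain
    artifact_rate: float = 2.0        # events / minute / subject
    artifact_scale: float = 8.0       # burst amplitude in channel SDs
    coupling_lag: float = 3.0         # s, feature leads gain by this much
    coupling_beta: float = 1.0
    device_offsets: Sequence[float] | None = None   # s per subject
    noise_scale: float = 1.0
    noise_corr: float = 0.3           # target inter-channel noise correlation
    mixing_jitter: float = 0.1        # per-subject deviation from the shared map
    blackout_time: float = 15.0       # s, stage blackout for the photoresistor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if not 0 < self.band.low < self.band.high < self.sample_rate / 2:
            raise ValueError("band must satisfy 0 < low < high < Nyquist")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * sample_rate must be an integer")
        if self.device_offsets is not None and \
                len(self.device_offsets) != self.n_subjects:
            raise ValueError("device_offsets length must equal n_subjects")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed).spawn(max(_STREAMS.values()) + 1)
        return np.random.default_rng(ss[_STREAMS[stream]])


@dataclass
class GroundTruth:
    """What the generator planted: recoverable by a correct pipeline."""

    source: np.ndarray                 # shared latent s(t) at sample rate
    gain: np.ndarray                   # engagement gain per second, in [0, 1]
    mixing: np.ndarray                 # n_subjects x n_channels, unit rows
    planted_lag: float
    artifact_times: list               # (subject index, time s)
    device_offsets: np.ndarray


def _channel_labels(n: int) -> list[str]:
    if n <= len(CHANNEL_LABELS_32):
        return CHANNEL_LABELS_32[:n]
    return CHANNEL_LABELS_32 + [f"EEG{i:03d}" for i in range(len(CHANNEL_LABELS_32), n)]


def _gain_per_second(config: SimConfig) -> np.ndarray:
    n_sec = int(np.ceil(config.duration)) + 1
    gp = config.gain_profile
    t = np.arange(n_sec, dtype=float)
    if callable(gp):
        g = np.asarray(gp(t), dtype=float)
    elif isinstance(gp, np.ndarray):
        g = np.asarray(gp, dtype=float)
        if len(g) < n_sec:
            g = np.pad(g, (0, n_sec - len(g)), mode="edge")
        g = g[:n_sec]
    elif gp == "constant":
        g = np.ones(n_sec)
    elif gp == "random_walk":
        rng = config.rng("gain")
        w = np.cumsum(rng.standard_normal(n_sec + 4 * int(config.gain_corr)))
        w = gaussian_filter1d(w, sigma=max(config.gain_corr / 2.0, 1.0))
        w = w[2 * int(config.gain_corr):2 * int(config.gain_corr) + n_sec]
        lo, hi = w.min(), w.max()
        g = (w - lo) / (hi - lo) if hi > lo else np.full(n_sec, 0.5)
    else:
        raise ValueError(f"unknown gain profile {gp!r}")
    return np.clip(g, 0.0, 1.0)


def _noise_sqrt(n_channels: int, rho: float) -> np.ndarray:
    """Symmetric square root of the uniform-correlation matrix
    (1-rho) I + rho J: unit channel variance, pairwise correlation rho."""
    eye = np.eye(n_channels)
    ones = np.ones((n_channels, n_channels)) / n_channels
    a = np.sqrt(1.0 - rho)                       # eigenvalue off the mean mode
    b = np.sqrt(1.0 - rho + rho * n_channels)    # eigenvalue of the mean mode
    return a * (eye - ones) + b * ones


def simulate_audience(config: SimConfig) -> tuple[GroupRecording, GroundTruth]:
    """Generate the audience and its ground truth.

    Deterministic for a fixed config seed. If ``device_offsets`` are set,
    each subject's content is shifted accordingly (subject k's recording
    starts ``offset_k`` seconds *before* the common clock), to be undone by
    the alignment stage.
    """
    rate = config.sample_rate
    T = config.n_samples
    offsets = np.zeros(config.n_subjects) if config.device_offsets is None \
        else np.asarray(config.device_offsets, dtype=float)
    pad_n = int(np.ceil(np.max(np.abs(offsets)) * rate)) if offsets.any() else 0
    T_ext = T + 2 * pad_n

    # shared band-limited source, unit variance
    rng_src = config.rng("source")
    s = _bandpass_array(rng_src.standard_normal(T_ext), config.band.low,
                        config.band.high, rate, config.band.order)
    s /= s.std()

    gain_sec = _gain_per_second(config)
    t_ext = (np.arange(T_ext) - pad_n) / rate
    gain_fine = np.interp(t_ext, np.arange(len(gain_sec), dtype=float), gain_sec)
    master = gain_fine * config.snr * s

    # per-subject unit-norm mixing: shared template plus small jitter
    rng_mix = config.rng("mixing")
    template = rng_mix.standard_normal(config.n_channels)
    template /= np.linalg.norm(template)
    jitter = rng_mix.standard_normal((config.n_subjects, config.n_channels))
    mixing = template[None, :] + config.mixing_jitter * jitter
    mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)

    csqrt = _noise_sqrt(config.n_channels, config.noise_corr)
    rng_noise = config.rng("noise")
    rng_art = config.rng("artifacts")
    labels = _channel_labels(config.n_channels)
    burst_n = int(round(0.2 * rate))
    recordings = []
    artifact_times: list[tuple[int, float]] = []
    for k in range(config.n_subjects):
        shift = int(round(offsets[k] * rate))
        a = pad_n - shift
        sig = mixing[k][:, None] * master[a:a + T][None, :]
        noise = config.noise_scale * (csqrt @ rng_noise.standard_normal(
            (config.n_channels, T)))
        x = sig + noise
        n_events = rng_art.poisson(config.artifact_rate * config.duration / 60.0)
        ch_sd = x.std(axis=1)
        for _ in range(n_events):
            t0 = rng_art.uniform(0, config.duration - 0.25)
            i0 = int(round(t0 * rate))
            chans = rng_art.random(config.n_channels) < 0.25
            if not chans.any():
                chans[rng_art.integers(config.n_channels)] = True
            amp = config.artifact_scale * ch_sd[chans] * \
                rng_art.choice([-1.0, 1.0], size=int(chans.sum()))
            x[chans, i0:i0 + burst_n] += amp[:, None]
            artifact_times.append((k, t0))
        recordings.append(Recording(subject_id=f"S{k + 1:02d}",
                                    channel_labels=list(labels),
                                    sample_rate=rate, samples=x))
    truth = GroundTruth(source=s[pad_n:pad_n + T] if pad_n else s,
                        gain=gain_sec[:int(np.ceil(config.duration))],
                        mixing=mixing, planted_lag=config.coupling_lag,
                        artifact_times=artifact_times,
                        device_offsets=offsets)
    group = GroupRecording(recordings, aligned=not offsets.any())
    return group, truth


def simulate_features(config: SimConfig, truth: GroundTruth,
                      n_independent: int = 1,
                      feature_noise: float = 0.1) -> dict[str, FeatureSeries]:
    """1 Hz feature series: one coupled to the engagement gain, plus
    independent controls.

    The coupled series f satisfies ``gain(t) = beta * f(t - lag) + noise``,
    i.e. the feature leads the gain by ``coupling_lag`` seconds. With
    ``coupling_beta == 0`` the "coupled" series is just another independent
    control.
    """
    lag = int(round(config.coupling_lag))
    if lag >= config.duration:
        raise ValueError("coupling_lag must be shorter than the recording")
    rng = config.rng("features")
    n = len(truth.gain)
    g = np.concatenate([truth.gain, np.full(lag, truth.gain[-1])])
    if config.coupling_beta != 0:
        coupled = g[lag:lag + n] / config.coupling_beta \
            + feature_noise * rng.standard_normal(n)
    else:
        coupled = gaussian_filter1d(rng.standard_normal(n + 20), sigma=3)[10:10 + n]
        coupled = (coupled - coupled.mean()) / max(coupled.std(), 1e-12)
    out = {"coupled": FeatureSeries("coupled", rate=1.0, values=coupled)}
    for j in range(n_independent):
        x = gaussian_filter1d(rng.standard_normal(n + 20), sigma=3)[10:10 + n]
        x = (x - x.mean()) / max(x.std(), 1e-12)
        out[f"indep_{j + 1}"] = FeatureSeries(f"indep_{j + 1}", rate=1.0, values=x)
    return out


def simulate_photoresistor(config: SimConfig, ramp: float = 0.5,
                           noise_sd: float = 0.01) -> list[np.ndarray]:
    """Per-subject light-sensor traces with a blackout ramp.

    Each trace sits at a high plateau and ramps linearly to a low level
    starting at ``blackout_time + device_offset`` on the device's own clock
    (a device that starts early sees the blackout later in its trace).
    """
    rate = config.sample_rate
    offsets = np.zeros(config.n_subjects) if config.device_offsets is None \
        else np.asarray(config.device_offsets, dtype=float)
    rng = config.rng("photoresistor")
    t = np.arange(config.n_samples) / rate
    traces = []
    for k in range(config.n_subjects):
        onset = config.blackout_time + offsets[k]
        level = np.interp(t, [0, onset, onset + ramp, t[-1] if len(t) else 0],
                          [1.0, 1.0, 0.1, 0.1])
        traces.append(level + noise_sd * rng.standard_normal(len(t)))
    return traces


def simulate_respiration(config: SimConfig, resp_freq: float = 0.25,
                         rate: float = 500.0,
                         noise_sd: float = 0.3) -> list[np.ndarray]:
    """Respiration-belt traces sharing a slow common rhythm.

    Subjects breathe around a common ``resp_freq`` oscillation with
    individual phase offsets and additive noise; sampled at the belt's own
    ``rate`` (clean with :func:`~audiencesync.preprocess.clean_respiration`).
    """
    rng = config.rng("respiration")
    n = int(round(config.duration * rate))
    t = np.arange(n) / rate
    common = np.sin(2 * np.pi * resp_freq * t)
    out = []
    for _ in range(config.n_subjects):
        phase = rng.normal(0, 0.3)
        out.append(np.sin(2 * np.pi * resp_freq * t + phase)
                   + 0.2 * common
                   + noise_sd * rng.standard_normal(n))
    return out


def simulate_coupled_series(n: int = 600, lag: int = 3, beta: float = 1.0,
                            n_predictors: int = 6, seed: int = 0,
                            ar: float = 0.3, pred_ar: float = 0.0
                            ) -> tuple[FeatureSeries, dict[str, FeatureSeries]]:
    """Stationary 1 Hz outcome/predictor set with one planted lagged driver.

    The outcome is an AR(1) process driven by predictor 1 at the planted
    lag: ``y_t = ar * y_{t-1} + beta * x1_{t-lag} + e_t``. Remaining
    predictors are independent AR(1) series. Predictors are temporally
    white by default (``pred_ar = 0``): an autocorrelated driver leaks
    into shorter lags through its own memory, so the planted lag is only
    exactly identifiable for a white driver. Used to exercise the Granger
    scan at the scale of the 1 Hz feature clock.
    """
    if lag < 1 or lag >= n:
        raise ValueError("lag must be in [1, n)")
    rng = np.random.default_rng(seed)

    def ar1(phi, size):
        e = rng.standard_normal(size)
        x = np.empty(size)
        x[0] = e[0] / np.sqrt(1 - phi ** 2)
        for i in range(1, size):
            x[i] = phi * x[i - 1] + e[i]
        return x / x.std()

    preds = {f"x{j + 1}": ar1(pred_ar, n) for j in range(n_predictors)}
    e = rng.standard_normal(n)
    y = np.empty(n)
    x1 = preds["x1"]
    y[0] = e[0]
    for i in range(1, n):
        drive = beta * x1[i - lag] if i >= lag else 0.0
        y[i] = ar * y[i - 1] + drive + e[i]
    outcome = FeatureSeries("outcome", rate=1.0, values=y)
    predictors = {k: FeatureSeries(k, rate=1.0, values=v)
                  for k, v in preds.items()}
    return outcome, predictors
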