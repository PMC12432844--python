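"""Continuous performance-feature extraction on a common 1 Hz clock.

Audio loudness (RMS energy), beat strength (a simplified autocorrelation
pulse-clarity index), dancer wrist acceleration, inter-dancer distance,
stage luminance, continuous engagement ratings, and audience respiration
synchrony all land on an identical 1 Hz grid so they can enter the Granger
coupling analysis against the windowed ISC time course.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import FeatureSeries, GroupRecording, Recording, WindowGrid
from .isc import ISCSeries, isc_timecourse
from . import isc as _isc

__all__ = ["rms_energy", "pulse_clarity", "accel_magnitude", "pair_distance",
           "luminance_series", "rolling_median", "window_ratings",
           "respiration_synchrony", "to_1hz"]


def to_1hz(times: np.ndarray, values: np.ndarray, duration: float | None = None,
           name: str = "", units: str = "") -> FeatureSeries:
    """Canonicalise an irregular/fast series to 1 Hz.

    Linear interpolation onto a 10 Hz grid followed by block-averaging over
    each 1 s interval; output sample t covers [t, t+1).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if duration is None:
        duration = float(times[-1]) + 1e-9
    n_sec = max(int(np.floor(duration)), 1)
    fine = np.arange(n_sec * 10) / 10.0
    interp = np.interp(fine, times, values)
    out = interp.reshape(n_sec, 10).mean(axis=1)
    return FeatureSeries(name=name, rate=1.0, values=out, units=units)


def rms_energy(audio: np.ndarray, rate: float,
               window: float = 0.050, overlap: float = 0.5) -> FeatureSeries:
    """Root-mean-square amplitude over 50 ms windows with 50 % overlap,
    interpolated to 1 Hz."""
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("empty audio")
    if rate < 8000:
        raise ValueError("audio rate must be >= 8 kHz")
    win_n = int(round(window * rate))
    hop_n = max(int(round(win_n * (1 - overlap))), 1)
    n_win = (len(audio) - win_n) // hop_n + 1
    if n_win < 1:
        raise ValueError("audio shorter than one RMS window")
    idx = np.arange(n_win)[:, None] * hop_n + np.arange(win_n)[None, :]
    rms = np.sqrt((audio[idx] ** 2).mean(axis=1))
    centers = (np.arange(n_win) * hop_n + win_n / 2) / rate
    return to_1hz(centers, rms, duration=len(audio) / rate,
                  name="audio_rms", units="amplitude")


def _onset_envelope(audio: np.ndarray, rate: float,
                    frame: float = 0.010) -> tuple[np.ndarray, float]:
    """Half-wave-rectified frame-energy difference (novelty) at 1/frame Hz."""
    frame_n = int(round(frame * rate))
    n = len(audio) // frame_n
    energy = (audio[:n * frame_n].reshape(n, frame_n) ** 2).mean(axis=1)
    onset = np.maximum(np.diff(energy, prepend=energy[0]), 0.0)
    return onset, 1.0 / frame


def pulse_clarity(audio: np.ndarray, rate: float,
                  window: float = 5.0, overlap: float = 0.1,
                  bpm_range: tuple[float, float] = (40.0, 200.0)) -> FeatureSeries:
    """Autocorrelation beat-strength index in [0, 1].

    Per 5 s window (10 % overlap): the onset envelope's autocorrelation is
    scanned over lags corresponding to 40-200 beats/min and the highest
    peak, normalised by lag 0, is the clarity. This is a deliberately
    simple index, not a re-implementation of any particular music-
    information-retrieval toolbox estimator.
    """
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        raise ValueError("empty audio")
    onset, env_rate = _onset_envelope(audio, rate)
    win_n = int(round(window * env_rate))
    hop_n = max(int(round(win_n * (1 - overlap))), 1)
    lag_lo = int(np.floor(60.0 / bpm_range[1] * env_rate))
    lag_hi = int(np.ceil(60.0 / bpm_range[0] * env_rate))
    times, values = [], []
    for a in range(0, len(onset) - win_n + 1, hop_n):
        w = onset[a:a + win_n] - onset[a:a + win_n].mean()
        if lag_hi * 2 > win_n or not w.any():
            times.append((a + win_n / 2) / env_rate)
            values.append(np.nan)
            continue
        ac = signal.correlate(w, w, mode="full")[len(w) - 1:]
        clarity = ac[lag_lo:lag_hi + 1].max() / ac[0] if ac[0] > 0 else 0.0
        times.append((a + win_n / 2) / env_rate)
        values.append(float(np.clip(clarity, 0.0, 1.0)))
    values = np.asarray(values)
    if np.isnan(values).any():
        ok = ~np.isnan(values)
        if not ok.any():
            raise ValueError("window too short for the slowest beat period")
        values = np.interp(np.arange(len(values)), np.flatnonzero(ok), values[ok])
    return to_1hz(np.asarray(times), values, duration=len(audio) / rate,
                  name="pulse_clarity")


def accel_magnitude(xyz_per_wrist: list[np.ndarray], rate: float,
                    times: np.ndarray | None = None) -> FeatureSeries:
    """Combined dancer acceleration.

    Each wrist's (3 x time) trace is resampled to a uniform 20 Hz clock,
    reduced to the root-summed-square magnitude, combined as the median
    across performers, and canonicalised to 1 Hz.
    """
    mags20 = []
    for xyz in xyz_per_wrist:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape[0] != 3:
            raise ValueError("each wrist trace must be 3 x time")
        t_in = np.arange(xyz.shape[1]) / rate if times is None else times
        t20 = np.arange(0.0, t_in[-1], 0.05)
        if times is not None and np.any(np.diff(t_in) > 1.0):
            import warnings
            warnings.warn("gap > 1 s in accelerometer data; interpolated")
        res = np.stack([np.interp(t20, t_in, ax) for ax in xyz])
        mags20.append(np.sqrt((res ** 2).sum(axis=0)))
    n = min(len(m) for m in mags20)
    combined = np.median(np.stack([m[:n] for m in mags20]), axis=0)
    return to_1hz(np.arange(n) * 0.05, combined, duration=n * 0.05,
                  name="accel", units="m/s^2")


def pair_distance(pos_a: np.ndarray, pos_b: np.ndarray, fps: float,
                  max_gap: float = 2.0) -> FeatureSeries:
    """Euclidean distance between two stage positions, per frame, then
    averaged over 5 s / 80 %-overlap windows and put on the 1 Hz clock.

    Missing coordinates (NaN) are linearly interpolated across gaps up to
    ``max_gap`` seconds; longer gaps stay missing.
    """
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    if pos_a.shape != pos_b.shape or pos_a.shape[1] != 2:
        raise ValueError("positions must be matching (time x 2) arrays")
    d = np.sqrt(((pos_a - pos_b) ** 2).sum(axis=1))
    bad = ~np.isfinite(d)
    if bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise ValueError("no valid position samples")
        filled = np.interp(np.arange(len(d)), good, d[good])
        runs = np.diff(np.concatenate([[0], bad.view(np.int8), [0]]))
        for s, e in zip(np.flatnonzero(runs == 1), np.flatnonzero(runs == -1)):
            if (e - s) / fps <= max_gap:
                d[s:e] = filled[s:e]
    t = np.arange(len(d)) / fps
    grid = WindowGrid(length=5.0, hop=1.0)
    starts = grid.starts(t[-1] + 1 / fps)
    means = np.array([
        np.nanmean(d[(t >= s) & (t < s + grid.length)]) for s in starts
    ]) if len(starts) else np.array([np.nanmean(d)])
    w_times = (starts + grid.length / 2) if len(starts) else np.array([t[-1] / 2])
    return to_1hz(w_times, means, duration=t[-1] + 1 / fps,
                  name="distance", units="m")


def luminance_series(frames: np.ndarray, fps: float) -> FeatureSeries:
    """Per-frame mean-luminance values interpolated to 1 Hz."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    frames = np.asarray(frames, dtype=float).ravel()
    t = np.arange(len(frames)) / fps
    return to_1hz(t, frames, duration=len(frames) / fps, name="luminance")


def rolling_median(series: np.ndarray, window: float, rate: float = 1.0) -> np.ndarray:
    """Centred rolling median; the window shrinks symmetrically at edges."""
    x = pd.Series(np.asarray(series, dtype=float))
    win = int(round(window * rate))
    if win > len(x):
        raise ValueError("window longer than the series")
    return x.rolling(win, center=True, min_periods=1).median().to_numpy()


def window_ratings(series: np.ndarray, rate: float,
                   length: float = 5.0, overlap: float = 0.8) -> FeatureSeries:
    """Mean rating per 5 s window with 80 % overlap — the ISC window grid."""
    if rate < 1.0:
        raise ValueError("rating must be sampled at >= 1 Hz")
    x = np.asarray(series, dtype=float).ravel()
    grid = WindowGrid.from_overlap(length, overlap)
    dur = len(x) / rate
    slices = grid.sample_slices(dur, rate)
    if not slices:
        raise ValueError("rating shorter than one window")
    vals = np.array([x[sl].mean() for sl in slices])
    return FeatureSeries(name="rating", rate=1.0 / grid.hop, values=vals)


def respiration_synchrony(traces: list[np.ndarray], rate: float = 250.0,
                          grid: WindowGrid | None = None) -> ISCSeries:
    """Audience respiration synchrony via the single-channel ISC pipeline.

    Each cleaned trace is one subject with one channel; with a single
    channel the component weight is trivially 1 and the windowed statistic
    reduces to the between/within covariance ratio of the traces under the
    same (N-1) normalisation as the EEG ISC.
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 respiration traces")
    n = min(len(t) for t in traces)
    recs = [Recording(subject_id=f"R{i + 1:02d}", channel_labels=["RESP"],
                      sample_rate=rate, samples=np.asarray(t[:n], dtype=float)[None, :])
            for i, t in enumerate(traces)]
    group = GroupRecording(recs, aligned=True)
    model = _isc.CCAModel(weights=np.ones((1, 1)), forward_models=np.ones((1, 1)),
                          Rw=np.ones((1, 1)), Rb=np.ones((1, 1)),
                          isc=np.ones(1), n_subjects=len(traces))
    series = isc_timecourse(group, model, grid or WindowGrid(),
                            components=1, band="respiration")[0]
    series.band = "respiration"
    return series
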