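"""Preprocessing: band-pass filtering, outlier zeroing, referencing,
resampling, and respiration cleaning.

Pipeline order is band-pass BEFORE outlier zeroing, so zeroed segments are
not smeared through the filter; both orders are possible by composing the
functions yourself. All filters are zero-phase (forward-backward) because
the downstream correlation and phase statistics are phase-sensitive.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import BandSpec, Recording

__all__ = [
    "bandpass_filter",
    "highpass_filter",
    "lowpass_filter",
    "zero_outliers",
    "common_average_reference",
    "resample",
    "clean_respiration",
]

logger = logging.getLogger(__name__)


def _bandpass_array(x: np.ndarray, low: float, high: float, rate: float,
                    order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def bandpass_filter(rec: Recording, band: BandSpec) -> Recording:
    """Zero-phase 5th-order Butterworth band-pass, per channel.

    Forward-backward application doubles the effective order but leaves the
    phase untouched; length is preserved.
    """
    band.validate_rate(rec.sample_rate)
    out = rec.copy()
    out.samples = _bandpass_array(rec.samples, band.low, band.high,
                                  rec.sample_rate, band.order)
    return out


def highpass_filter(rec: Recording, cutoff: float, order: int = 5) -> Recording:
    """Optional broadband high-pass (zero-phase Butterworth)."""
    if not 0 < cutoff < rec.sample_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=rec.sample_rate,
                        output="sos")
    out = rec.copy()
    out.samples = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return out


def lowpass_filter(rec: Recording, cutoff: float, order: int = 5) -> Recording:
    """Optional broadband low-pass (zero-phase Butterworth)."""
    if not 0 < cutoff < rec.sample_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=rec.sample_rate,
                        output="sos")
    out = rec.copy()
    out.samples = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return out


def zero_outliers(rec: Recording, sd_threshold: float = 4.0,
                  pad: float = 0.040) -> tuple[Recording, float]:
    """Zero samples beyond ``sd_threshold`` channel SDs, plus ``pad`` s of
    context on each side, and flag them in the mask.

    Statistics are computed per channel over the currently unmasked samples
    of the full recording. Returns the recording and the fraction of
    channel-samples newly-or-previously zeroed.
    """
    if rec.n_samples < 1:
        raise ValueError("recording has no samples")
    out = rec.copy()
    if out.mask is None:
        out.mask = np.zeros_like(out.samples, dtype=bool)
    pad_n = int(round(pad * rec.sample_rate))
    kernel = np.ones(2 * pad_n + 1, dtype=bool)
    for c in range(out.n_channels):
        x = out.samples[c]
        keep = ~out.mask[c]
        if not keep.any():
            continue
        mu = x[keep].mean()
        sd = x[keep].std()
        if sd == 0:
            logger.warning("channel %s is constant; no outliers flagged",
                           out.channel_labels[c])
            continue
        hits = keep & (np.abs(x - mu) > sd_threshold * sd)
        if hits.any():
            if pad_n > 0:
                hits = np.convolve(hits, kernel, mode="same") > 0
            out.mask[c] |= hits
    out.samples[out.mask] = 0.0
    frac = float(out.mask.mean())
    return out, frac


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the across-channel mean at every sample."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs >= 2 channels")
    out = rec.copy()
    out.samples = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return out


def resample(rec: Recording, target: float) -> Recording:
    """Anti-aliased polyphase downsampling to ``target`` Hz.

    Upsampling is refused: the pipeline only ever moves 500 -> 250 Hz.
    """
    if target > rec.sample_rate:
        raise ValueError("upsampling is not supported")
    if target == rec.sample_rate:
        return rec.copy()
    frac = Fraction(target / rec.sample_rate).limit_denominator(1000)
    out = rec.copy()
    out.samples = signal.resample_poly(rec.samples, frac.numerator,
                                       frac.denominator, axis=-1)
    out.sample_rate = target
    if rec.mask is not None:
        # nearest-neighbour carry-over of the outlier mask
        idx = np.minimum(
            (np.arange(out.samples.shape[1]) * rec.sample_rate / target)
            .round().astype(int),
            rec.n_samples - 1,
        )
        out.mask = rec.mask[:, idx]
    return out


def clean_respiration(trace: np.ndarray, rate: float,
                      target: float = 250.0) -> np.ndarray:
    """Respiration-belt cleaning.

    Downsample to ``target`` Hz, replace outliers falling outside a moving
    0.5 s median corridor with the surrounding average, then smooth with a
    1 s Savitzky-Golay filter (polynomial order 3).
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if len(trace) / rate < 1.0:
        raise ValueError("respiration trace must be at least 1 s long")
    if rate < target:
        raise ValueError("respiration rate must be >= target rate")
    if rate > target:
        frac = Fraction(target / rate).limit_denominator(1000)
        trace = signal.resample_poly(trace, frac.numerator, frac.denominator,
                                     padtype="line")
    win = int(round(0.5 * target))
    if win % 2 == 0:
        win += 1
    med = signal.medfilt(trace, kernel_size=win)
    resid = trace - med
    sd = resid.std()
    if sd > 0:
        bad = np.abs(resid) > 4.0 * sd
        if bad.any():
            # surrounding average: interpolate across the flagged run
            good = ~bad
            trace = trace.copy()
            trace[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good),
                                   trace[good])
    sg_win = int(round(1.0 * target))
    if sg_win % 2 == 0:
        sg_win += 1
    sg_win = min(sg_win, len(trace) if len(trace) % 2 else len(trace) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = signal.savgol_filter(trace, sg_win, polyorder=3)
    return out
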