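"""Pairwise phase-locking value (PLV) and Welch band power.

PLV between subjects j and k over a window w of T samples is the modulus
of the mean unit phasor of their instantaneous phase difference,

    PLV_jk(w) = | (1/T) sum_{t in w} exp(i (theta_j(t) - theta_k(t))) |,

with phases taken as the angle of the analytic (Hilbert) signal of
band-passed data. 1 means perfect phase locking, 0 none. Band power uses
Welch's method with 1 s Hann segments and 20 % overlap, averaged across
channels and then across band bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal

from .containers import BandSpec, GroupRecording, Recording

__all__ = ["instantaneous_phase", "plv_pairwise", "section_plv",
           "welch_band_power", "power_outlier_filter",
           "CENTRAL_ELECTRODES", "OCCIPITAL_ELECTRODES", "ANALYSIS_ELECTRODES"]

logger = logging.getLogger(__name__)

CENTRAL_ELECTRODES = ("C3", "C4", "Cz")
OCCIPITAL_ELECTRODES = ("O1", "Oz", "O2")
ANALYSIS_ELECTRODES = CENTRAL_ELECTRODES + OCCIPITAL_ELECTRODES


def _electrode_region(name: str) -> str:
    if name in CENTRAL_ELECTRODES:
        return "central"
    if name in OCCIPITAL_ELECTRODES:
        return "occipital"
    return "other"


def instantaneous_phase(rec: Recording, broadband_warn_hz: float = 25.0
                        ) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) per channel.

    The input must be band-passed: phase of a broadband signal is
    ill-defined. A crude spectral-width check warns when the input looks
    broadband (power-weighted bandwidth above ``broadband_warn_hz``).
    """
    x = rec.samples
    # spectral-width heuristic on the first channel
    f, psd = signal.welch(x[0], fs=rec.sample_rate,
                          nperseg=min(1024, x.shape[1]))
    if psd.sum() > 0:
        centroid = (f * psd).sum() / psd.sum()
        width = np.sqrt((((f - centroid) ** 2) * psd).sum() / psd.sum())
        if 2 * width > broadband_warn_hz:
            warnings.warn("input looks broadband; instantaneous phase is "
                          "ill-defined — band-pass first")
    return np.angle(signal.hilbert(x, axis=-1))


def plv_pairwise(theta_j: np.ndarray, theta_k: np.ndarray, rate: float,
                 window: float = 5.0, hop: float = 1.0,
                 mask_j: np.ndarray | None = None,
                 mask_k: np.ndarray | None = None,
                 max_masked: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Windowed PLV between two phase series.

    Windows are ``window`` s long with ``hop`` s hop (default 5 s windows,
    4 s overlap). Windows where more than ``max_masked`` of the samples are
    masked for either subject are NaN. Returns (window start times, PLV).
    """
    theta_j = np.asarray(theta_j, dtype=float).ravel()
    theta_k = np.asarray(theta_k, dtype=float).ravel()
    if theta_j.shape != theta_k.shape:
        raise ValueError("phase series must have equal length")
    win_n = int(round(window * rate))
    hop_n = max(int(round(hop * rate)), 1)
    if win_n > len(theta_j):
        raise ValueError("window longer than the series")
    phasor = np.exp(1j * (theta_j - theta_k))
    bad = np.zeros(len(theta_j), dtype=bool)
    if mask_j is not None:
        bad |= np.asarray(mask_j, dtype=bool)
    if mask_k is not None:
        bad |= np.asarray(mask_k, dtype=bool)
    starts = np.arange(0, len(theta_j) - win_n + 1, hop_n)
    plv = np.empty(len(starts))
    for i, a in enumerate(starts):
        sl = slice(a, a + win_n)
        keep = ~bad[sl]
        if keep.mean() < 1.0 - max_masked:
            plv[i] = np.nan
            continue
        plv[i] = np.abs(phasor[sl][keep].mean())
    return starts / rate, plv


def section_plv(group: GroupRecording, sections: dict[str, tuple[float, float]],
                electrodes: tuple[str, ...] = ANALYSIS_ELECTRODES,
                window: float = 5.0, hop: float = 1.0,
                non_overlapping: bool = False) -> pd.DataFrame:
    """PLV rows for every subject pair, electrode and window per section.

    ``sections`` maps a label to a (start, stop) interval in seconds. The
    default grid is 5 s windows with 4 s overlap; ``non_overlapping``
    switches to back-to-back 5 s windows (36 windows per 3 min section).
    The input group must already be band-passed to the band of interest.
    """
    labels = group.channel_labels
    for el in electrodes:
        if el not in labels:
            raise ValueError(f"unknown electrode {el!r}")
    if non_overlapping:
        hop = window
    rate = group.sample_rate
    phases = [instantaneous_phase(r) for r in group.recordings]
    rows = []
    for sec_name, (t0, t1) in sections.items():
        if not (0 <= t0 < t1 <= group.duration):
            raise ValueError(f"section {sec_name!r} outside recording span")
        a, b = int(round(t0 * rate)), int(round(t1 * rate))
        if (b - a) / rate < window:
            logger.warning("section %s shorter than one window; empty",
                           sec_name)
            continue
        for el in electrodes:
            c = labels.index(el)
            for j, k in combinations(range(group.n_subjects), 2):
                mj = group.recordings[j].mask
                mk = group.recordings[k].mask
                times, plv = plv_pairwise(
                    phases[j][c, a:b], phases[k][c, a:b], rate,
                    window=window, hop=hop,
                    mask_j=None if mj is None else mj[c, a:b],
                    mask_k=None if mk is None else mk[c, a:b])
                for t, v in zip(times, plv):
                    rows.append({
                        "section": sec_name,
                        "pair": (group.recordings[j].subject_id,
                                 group.recordings[k].subject_id),
                        "electrode": el,
                        "region": _electrode_region(el),
                        "window_start_s": t0 + t,
                        "plv": v,
                    })
    return pd.DataFrame(rows)


def welch_band_power(rec: Recording, band: BandSpec,
                     section: tuple[float, float] | None = None,
                     nperseg: int = 250, noverlap: int = 50) -> float:
    """Mean band power (signal units^2 / Hz) via Welch's method.

    1 s (250-sample) Hann segments with 20 % overlap, PSD averaged across
    channels, then averaged over the band's frequency bins.
    """
    x = rec.samples
    if section is not None:
        a = int(round(section[0] * rec.sample_rate))
        b = int(round(section[1] * rec.sample_rate))
        if (b - a) < rec.sample_rate:
            raise ValueError("section must be at least 1 s long")
        x = x[:, a:b]
    f, psd = signal.welch(x, fs=rec.sample_rate, window="hann",
                          nperseg=nperseg, noverlap=noverlap, axis=-1)
    mean_psd = psd.mean(axis=0)
    in_band = (f >= band.low) & (f <= band.high)
    if not in_band.any():
        raise ValueError("no frequency bin falls inside the band")
    return float(mean_psd[in_band].mean())


def group_band_power(group: GroupRecording, band: BandSpec,
                     sections: dict[str, tuple[float, float]] | None = None
                     ) -> pd.DataFrame:
    """Per-subject (and per-section) Welch band power table."""
    secs = sections or {"all": (0.0, group.duration)}
    rows = []
    for rec in group.recordings:
        for name, span in secs.items():
            rows.append({"subject": rec.subject_id, "band": band.name,
                         "section": name,
                         "power": welch_band_power(rec, band, span)})
    return pd.DataFrame(rows)


def power_outlier_filter(rows: pd.DataFrame, sd: float = 4.0
                         ) -> tuple[pd.DataFrame, int]:
    """Drop rows whose power is beyond mean +/- ``sd`` SDs.

    Returns the filtered table and the number of rows removed. Idempotent
    in the sense that re-filtering the output removes rows only if the
    trimmed statistics expose new outliers (none for homogeneous data).
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 rows to estimate outlier bounds")
    p = rows["power"].to_numpy(dtype=float)
    mu, sigma = p.mean(), p.std()
    if sigma == 0:
        return rows.copy(), 0
    keep = np.abs(p - mu) <= sd * sigma
    return rows.loc[keep].reset_index(drop=True), int((~keep).sum())
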