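"""Core data containers shared across the analysis pipeline.

The atomic object is a :class:`Recording` (one subject, channels x samples);
a :class:`GroupRecording` stacks aligned subjects and is the input to every
synchrony computation. :class:`BandSpec` and :class:`WindowGrid` carry the
canonical band definitions and the 5 s / 80 %-overlap windowing used for all
time-resolved statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "GroupRecording",
    "BandSpec",
    "WindowGrid",
    "FeatureSeries",
    "BANDS",
    "band",
]


@dataclass
class BandSpec:
    """A frequency band for zero-phase Butterworth band-pass filtering.

    Canonical bands: delta 1-4, theta 4-8, alpha 8-12, beta 12-20 Hz.
    """

    name: str
    low: float
    high: float
    order: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges: ({self.low}, {self.high})")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_rate(self, sample_rate: float) -> None:
        if self.high >= sample_rate / 2:
            raise ValueError(
                f"band {self.name} high edge {self.high} Hz >= Nyquist "
                f"({sample_rate / 2} Hz)"
            )


BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 12.0),
    "beta": BandSpec("beta", 12.0, 20.0),
}

#: Band ordering used for cross-band cluster adjacency.
BAND_ORDER = ("delta", "theta", "alpha", "beta")


def band(name: str) -> BandSpec:
    """Look up a canonical band by name."""
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; choose from {sorted(BANDS)}") from None


@dataclass
class Recording:
    """One subject's multichannel record.

    Parameters
    ----------
    subject_id
        Subject label.
    channel_labels
        Electrode names (10/10 convention for EEG).
    sample_rate
        Sampling rate in Hz.
    samples
        channels x time array (microvolts for EEG).
    mask
        Boolean array, same shape as ``samples``; True marks samples that
        were zeroed as outliers and must be excluded from windowed
        statistics.
    """

    subject_id: str
    channel_labels: list[str]
    sample_rate: float
    samples: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match samples rows")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.samples.shape:
                raise ValueError("mask shape must match samples shape")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def copy(self) -> "Recording":
        return replace(
            self,
            channel_labels=list(self.channel_labels),
            samples=self.samples.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )

    def valid_samples(self) -> np.ndarray:
        """Per-sample validity: True where no channel is masked."""
        if self.mask is None:
            return np.ones(self.n_samples, dtype=bool)
        return ~self.mask.any(axis=0)


@dataclass
class GroupRecording:
    """An aligned multi-subject stack of recordings.

    All subjects must share channel labels, sample rate and length once
    aligned. ``aligned`` is set by the alignment stage (or by the simulator
    when device offsets are zero).
    """

    recordings: list[Recording]
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.recordings) < 2:
            raise ValueError("a group needs at least 2 subjects")
        r0 = self.recordings[0]
        for r in self.recordings[1:]:
            if r.sample_rate != r0.sample_rate:
                raise ValueError("subjects differ in sample rate")
            if r.channel_labels != r0.channel_labels:
                raise ValueError("subjects differ in channel labels")

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    @property
    def sample_rate(self) -> float:
        return self.recordings[0].sample_rate

    @property
    def channel_labels(self) -> list[str]:
        return self.recordings[0].channel_labels

    @property
    def n_channels(self) -> int:
        return self.recordings[0].n_channels

    @property
    def n_samples(self) -> int:
        n = {r.n_samples for r in self.recordings}
        if len(n) != 1:
            raise ValueError("subjects differ in length; align/trim first")
        return n.pop()

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def data(self) -> np.ndarray:
        """Stack as a subjects x channels x time array."""
        return np.stack([r.samples for r in self.recordings])

    def validity(self) -> np.ndarray:
        """subjects x time boolean, True where a sample is usable."""
        return np.stack([r.valid_samples() for r in self.recordings])

    def map(self, fn) -> "GroupRecording":
        """Apply a Recording -> Recording function to every subject."""
        return GroupRecording([fn(r) for r in self.recordings], aligned=self.aligned)


@dataclass
class WindowGrid:
    """Sliding-window grid: 5 s windows with 80 % overlap (1 s hop) by default.

    Windows are half-open ``[start, start + length)`` at sample resolution
    and must lie entirely within the recording span.
    """

    length: float = 5.0
    hop: float = 1.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.hop <= 0:
            raise ValueError("window length and hop must be positive")

    @classmethod
    def from_overlap(cls, length: float = 5.0, overlap: float = 0.8) -> "WindowGrid":
        if not 0 <= overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        return cls(length=length, hop=length * (1.0 - overlap))

    def starts(self, duration: float) -> np.ndarray:
        """Window start times (s) fitting within ``duration``."""
        if duration < self.length:
            return np.empty(0)
        n = int(np.floor((duration - self.length) / self.hop + 1e-9)) + 1
        return np.arange(n) * self.hop

    def n_windows(self, duration: float) -> int:
        return len(self.starts(duration))

    def sample_slices(self, duration: float, rate: float) -> list[slice]:
        """Half-open sample index slices for each window."""
        length_n = int(round(self.length * rate))
        return [
            slice(int(round(s * rate)), int(round(s * rate)) + length_n)
            for s in self.starts(duration)
        ]


@dataclass
class FeatureSeries:
    """A uniformly sampled 1-D series (performance feature, rating, ...)."""

    name: str
    rate: float
    values: np.ndarray
    units: str = ""
    start: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate

    def spectral_centroid(self) -> float:
        """Power-weighted mean frequency (Hz) of the series.

        Reported for each feature so users can judge whether its power lies
        outside the EEG band of interest; no threshold is asserted.
        """
        x = self.values - np.mean(self.values)
        if not np.any(x):
            return 0.0
        psd = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), d=1.0 / self.rate)
        return float(np.sum(freqs * psd) / np.sum(psd))
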