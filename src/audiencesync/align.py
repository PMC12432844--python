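"""Temporal alignment of independently clocked devices.

Each device carries a photoresistor whose trace drops sharply at the first
stage blackout. The onset of that drop — the first change in the slope of
the trace — is detected per device by a two-segment least-squares scan, and
all recordings are shifted toward the device whose onset is most central
(minimum summed absolute difference to the others), then trimmed to the
jointly observed span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GroupRecording, Recording

__all__ = ["ChangePoint", "NoChangePointError", "SuspiciousOffsetError",
           "detect_light_onset", "align_recordings"]


class NoChangePointError(ValueError):
    """No breakpoint reduced the fit residual enough to count as a slope change."""


class SuspiciousOffsetError(ValueError):
    """An implied shift is implausibly large relative to the recording."""


@dataclass
class ChangePoint:
    time: float          # seconds from trace start
    kind: str = "slope-change"
    score: float = 0.0   # relative residual reduction vs a single-line fit


def _segment_sse(prefix: dict[str, np.ndarray], a: int, b: int) -> float:
    """SSE of the least-squares line fit on samples [a, b) from prefix sums."""
    n = b - a
    if n < 2:
        return 0.0
    sx = prefix["x"][b] - prefix["x"][a]
    sy = prefix["y"][b] - prefix["y"][a]
    sxx = prefix["xx"][b] - prefix["xx"][a]
    sxy = prefix["xy"][b] - prefix["xy"][a]
    syy = prefix["yy"][b] - prefix["yy"][a]
    den = n * sxx - sx * sx
    if den <= 0:
        return 0.0
    slope = (n * sxy - sx * sy) / den
    # SSE = Syy_c - slope * Sxy_c with centred second moments
    syy_c = syy - sy * sy / n
    sxy_c = sxy - sx * sy / n
    return float(max(syy_c - slope * sxy_c, 0.0))


def detect_light_onset(trace: np.ndarray, rate: float,
                       threshold: float = 0.2,
                       min_segment: float = 0.5) -> ChangePoint:
    """Find the earliest slope change in a photoresistor trace.

    Scans two-segment least-squares fits over every candidate breakpoint
    (O(n) via prefix sums) and returns the first local optimum whose
    residual reduction relative to the single-line fit exceeds
    ``threshold`` (default 20 %).
    """
    y = np.asarray(trace, dtype=float).ravel()
    n = len(y)
    if n / rate < 10.0:
        raise ValueError("photoresistor trace must be at least 10 s long")
    x = np.arange(n, dtype=float)
    prefix = {
        "x": np.concatenate([[0.0], np.cumsum(x)]),
        "y": np.concatenate([[0.0], np.cumsum(y)]),
        "xx": np.concatenate([[0.0], np.cumsum(x * x)]),
        "xy": np.concatenate([[0.0], np.cumsum(x * y)]),
        "yy": np.concatenate([[0.0], np.cumsum(y * y)]),
    }
    sse_total = _segment_sse(prefix, 0, n)
    if sse_total == 0:
        raise NoChangePointError("trace is perfectly linear; no slope change")
    margin = max(int(round(min_segment * rate)), 2)

    right_margin = max(margin // 4, 8)

    def best_break(b: int) -> tuple[int, float]:
        """Best two-segment breakpoint on [0, b); returns (k, score)."""
        total = _segment_sse(prefix, 0, b)
        if total <= 0 or b < 2 * margin:
            return -1, 0.0
        ks = np.arange(margin, b - right_margin)
        sse = np.array([_segment_sse(prefix, 0, k) + _segment_sse(prefix, k, b)
                        for k in ks])
        i = int(np.argmin(sse))
        return int(ks[i]), float(1.0 - sse[i] / total)

    k, score = best_break(n)
    if k < 0 or score < threshold:
        raise NoChangePointError(
            f"no breakpoint reduces residual by >= {threshold:.0%}")
    # the global optimum of a multi-kink trace (plateau -> ramp -> floor)
    # can sit mid-ramp; restricting to data up to just past the current
    # estimate and re-fitting walks it back to the earliest slope change
    for _ in range(20):
        k2, s2 = best_break(min(k + margin, n))
        if k2 < 0 or s2 < threshold or k2 >= k:
            break
        k = k2
        score = s2
    return ChangePoint(time=float(k / rate), score=score)


def align_recordings(group: GroupRecording,
                     onsets: list[ChangePoint],
                     max_shift_frac: float = 0.10) -> tuple[GroupRecording, np.ndarray]:
    """Shift every subject toward the reference blackout onset and trim.

    The reference is the subject whose onset minimises the summed absolute
    onset difference to all others. Each recording is shifted by
    (reference onset - own onset); overhanging samples are trimmed so all
    recordings share a common span. Returns the aligned group and the
    applied shifts in seconds.
    """
    if len(onsets) != group.n_subjects:
        raise ValueError("need exactly one onset per subject")
    rate = group.sample_rate
    t = np.array([o.time for o in onsets])
    ref = int(np.argmin(np.abs(t[:, None] - t[None, :]).sum(axis=1)))
    shifts_s = t[ref] - t
    shifts_n = np.round(shifts_s * rate).astype(int)
    for r, s in zip(group.recordings, shifts_s):
        if abs(s) > max_shift_frac * r.duration:
            raise SuspiciousOffsetError(
                f"shift {s:.2f} s exceeds {max_shift_frac:.0%} of duration for "
                f"subject {r.subject_id}")
    # physical time of sample i in record k is i/rate - t_k; the jointly
    # observed span starts at -min(t), so drop (t_k - min t) samples from
    # each head and trim tails to a common length
    heads = np.round((t - t.min()) * rate).astype(int)
    lengths = np.array([r.n_samples for r in group.recordings]) - heads
    common = int(lengths.min())
    aligned = []
    for r, h in zip(group.recordings, heads):
        out = r.copy()
        out.samples = out.samples[:, h:h + common]
        if out.mask is not None:
            out.mask = out.mask[:, h:h + common]
        aligned.append(out)
    return GroupRecording(aligned, aligned=True), shifts_n / rate
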