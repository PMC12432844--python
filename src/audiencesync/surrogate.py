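"""Circular-shift surrogate nulls, cluster-based correction, and the
resting-state baseline test.

The null model rotates each subject's full multichannel record by an
independent random offset. This destroys the temporal alignment between
subjects (hence any genuine inter-subject correlation) while preserving
each subject's spectrum, autocorrelation and artifact structure. The
time-resolved ISC pipeline is re-run on each surrogate, giving per-window
null draws; cluster correction compares supra-threshold runs of the true
series against the distribution of the largest cluster per surrogate
iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .containers import BAND_ORDER, GroupRecording, WindowGrid
from .isc import (CCAModel, ISCSeries, _cov_arrays, _windowed_isc, fit_cca,
                  isc_timecourse, pooled_covariances)

__all__ = ["NullDistribution", "Cluster", "ClusterSet", "circular_shift",
           "null_isc_distribution", "significant_clusters",
           "rs_baseline_test", "fdr_bh"]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Per-window ISC1 draws under the circular-shift null."""

    draws: np.ndarray            # iterations x windows
    grid: WindowGrid
    band: str = ""
    level: float = 95.0

    @property
    def iterations(self) -> int:
        return self.draws.shape[0]

    def percentile_curve(self, level: float | None = None) -> np.ndarray:
        lv = self.level if level is None else level
        return np.nanpercentile(self.draws, lv, axis=0)


@dataclass
class Cluster:
    band: str
    start_window: int
    end_window: int              # inclusive
    size: int
    significant: bool = False


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold: float = 0.0       # 95th percentile of null max cluster sizes

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def circular_shift(group: GroupRecording, seed=None,
                   min_offset: float = 30.0,
                   offsets: np.ndarray | None = None) -> GroupRecording:
    """Rotate each subject's record by an independent random offset.

    Offsets are uniform on [min_offset, duration - min_offset] seconds
    unless given explicitly; the whole channels x time matrix (and mask)
    rotates together so within-subject structure is preserved exactly.
    """
    dur = group.duration
    if offsets is None:
        if dur < 4 * min_offset:
            raise ValueError(
                f"duration {dur:.0f} s too short for circular-shift offsets "
                f">= {min_offset:.0f} s")
        rng = np.random.default_rng(seed)
        offsets = rng.uniform(min_offset, dur - min_offset, group.n_subjects)
    offsets = np.asarray(offsets, dtype=float)
    rate = group.sample_rate
    shifted = []
    for rec, off in zip(group.recordings, offsets):
        k = int(round(off * rate)) % rec.n_samples
        out = rec.copy()
        out.samples = np.roll(out.samples, k, axis=1)
        if out.mask is not None:
            out.mask = np.roll(out.mask, k, axis=1)
        shifted.append(out)
    return GroupRecording(shifted, aligned=group.aligned)


def null_isc_distribution(group: GroupRecording, grid: WindowGrid | None = None,
                          iterations: int = 1000, seed=None,
                          band: str = "", reg: float = 0.1,
                          level: float = 95.0) -> NullDistribution:
    """Surrogate distribution of windowed ISC1.

    Each iteration re-runs the full pipeline on circularly shifted data:
    shift -> pooled covariances -> CCA fit -> windowed ISC with that
    iteration's own first component.
    """
    if iterations < 10:
        raise ValueError("need at least 10 surrogate iterations")
    if iterations < 100:
        logger.warning("only %d surrogate iterations; percentile estimates "
                       "will be coarse", iterations)
    if grid is None:
        grid = WindowGrid()
    dur = group.duration
    if dur < 120.0:
        raise ValueError("duration < 120 s; circular-shift offsets degenerate")
    rng = np.random.default_rng(seed)
    rate = group.sample_rate
    X = group.data()
    V = group.validity()
    all_valid = bool(V.all())
    slices = grid.sample_slices(dur, rate)
    starts_n = np.array([sl.start for sl in slices])
    L = slices[0].stop - slices[0].start
    n_sub, _, n_t = X.shape
    draws = np.empty((iterations, len(slices)))
    for it in range(iterations):
        offs = rng.uniform(30.0, dur - 30.0, n_sub)
        offs_n = (np.round(offs * rate).astype(int)) % n_t
        Xr = np.stack([np.roll(X[k], offs_n[k], axis=-1)
                       for k in range(n_sub)])
        Vr = None if all_valid else np.stack(
            [np.roll(V[k], offs_n[k]) for k in range(n_sub)])
        Rw, Rb = _cov_arrays(Xr, Vr)
        model = fit_cca(Rw, Rb, n_sub, n_components=1, reg=reg)
        y = np.einsum("c,kct->kt", model.weights[:, 0], Xr)
        draws[it] = _windowed_isc(y, Vr, starts_n, L, n_sub, 0.5)
    return NullDistribution(draws=draws, grid=grid, band=band, level=level)


def _label_clusters(exceed: np.ndarray) -> tuple[np.ndarray, int]:
    """Connected components over a bands x windows boolean matrix.

    Adjacency: contiguous windows within a band, plus the same window in a
    neighbouring band (4-connectivity).
    """
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return ndimage.label(exceed, structure=structure)


def significant_clusters(true_series: dict[str, ISCSeries] | ISCSeries,
                         null: dict[str, NullDistribution] | NullDistribution,
                         level: float = 95.0) -> ClusterSet:
    """Cluster-corrected exceedance of the surrogate percentile curve.

    Supra-threshold windows (true ISC1 above the per-window ``level``
    percentile of the null draws) are grouped by adjacency in time and
    across neighbouring frequency bands. The null cluster distribution
    takes the largest such cluster from each surrogate iteration (each
    iteration's draws thresholded against the same percentile curve); a
    true cluster is significant iff its size exceeds the 95th percentile
    of the null maxima.
    """
    if isinstance(true_series, ISCSeries):
        true_series = {true_series.band or "band": true_series}
    if isinstance(null, NullDistribution):
        if len(true_series) != 1:
            raise ValueError("one NullDistribution given for several bands")
        null = {next(iter(true_series)): null}
    bands = [b for b in BAND_ORDER if b in true_series]
    if not bands:
        bands = list(true_series)
    n_windows = {len(true_series[b].values) for b in bands}
    if len(n_windows) != 1:
        raise ValueError("bands have mismatched window grids")
    n_win = n_windows.pop()
    iters = {null[b].iterations for b in bands}
    if len(iters) != 1:
        raise ValueError("null distributions have mismatched iteration counts")
    n_iter = iters.pop()

    thresh = np.stack([null[b].percentile_curve(level) for b in bands])
    true_mat = np.stack([true_series[b].values for b in bands])
    if any(null[b].draws.shape[1] != n_win for b in bands):
        raise ValueError("null grid does not match the true series grid")
    exceed = np.where(np.isnan(true_mat), False, true_mat > thresh)

    labels, n_lab = _label_clusters(exceed)
    clusters = []
    for lab in range(1, n_lab + 1):
        rows, cols = np.nonzero(labels == lab)
        for bi in np.unique(rows):
            sel = cols[rows == bi]
            clusters.append(Cluster(band=bands[bi],
                                    start_window=int(sel.min()),
                                    end_window=int(sel.max()),
                                    size=int((labels == lab).sum())))
    # null: largest cluster per iteration across the same band stack
    null_max = np.zeros(n_iter)
    draws = np.stack([null[b].draws for b in bands])  # bands x iters x windows
    for it in range(n_iter):
        ex = draws[:, it, :] > thresh
        lab, nl = _label_clusters(ex)
        if nl:
            null_max[it] = np.bincount(lab.ravel())[1:].max()
    cluster_thresh = float(np.percentile(null_max, 95)) if n_iter else 0.0
    for c in clusters:
        c.significant = c.size > cluster_thresh
    return ClusterSet(clusters=clusters, null_max_sizes=null_max,
                      threshold=cluster_thresh)


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejections at level q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def rs_baseline_test(perf_isc: ISCSeries, rs_group: GroupRecording,
                     segment_length: float = 150.0, reg: float = 0.1,
                     grid: WindowGrid | None = None,
                     min_windows: int = 6):
    """Compare performance ISC against a tiled resting-state baseline.

    The resting-state record is tiled end-to-end to the performance length,
    run through the same CCA/windowed-ISC pipeline, and each consecutive
    ``segment_length`` block of performance windows is compared to the
    matching resting-state windows with a paired Wilcoxon signed-rank test;
    p-values are BH-FDR corrected across segments.

    Returns a list of dicts with segment start (s), statistic, p, p_fdr and
    direction ('performance' or 'rest' for whichever median is larger).
    """
    if grid is None:
        grid = perf_isc.grid
    perf_dur = (len(perf_isc.values) - 1) * grid.hop + grid.length
    if rs_group.duration < segment_length:
        raise ValueError("resting-state recording shorter than one segment")
    # tile RS to cover the performance span
    reps = int(np.ceil(perf_dur / rs_group.duration))

    def tile(rec):
        out = rec.copy()
        out.samples = np.tile(out.samples, (1, reps))
        if out.mask is not None:
            out.mask = np.tile(out.mask, (1, reps))
        n = int(round(perf_dur * rec.sample_rate))
        out.samples = out.samples[:, :n]
        if out.mask is not None:
            out.mask = out.mask[:, :n]
        return out

    tiled = rs_group.map(tile)
    Rw, Rb = pooled_covariances(tiled)
    model = fit_cca(Rw, Rb, tiled.n_subjects, n_components=1, reg=reg)
    rs_series = isc_timecourse(tiled, model, grid, components=1,
                               band=perf_isc.band)[0]
    n_win = min(len(perf_isc.values), len(rs_series.values))
    per_seg = max(int(round(segment_length / grid.hop)), 1)
    results = []
    for a in range(0, n_win, per_seg):
        b = min(a + per_seg, n_win)
        x = perf_isc.values[a:b]
        y = rs_series.values[a:b]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_windows:
            logger.warning("segment at %.0f s has %d valid windows; skipped",
                           a * grid.hop, int(ok.sum()))
            continue
        d = x[ok] - y[ok]
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            mode = "exact" if ok.sum() < 25 else "approx"
            stat, p = stats.wilcoxon(x[ok], y[ok], correction=(mode == "approx"),
                                     method=mode)
        results.append({
            "segment_start_s": a * grid.hop,
            "statistic": float(stat),
            "p": float(p),
            "direction": "performance" if np.median(d) > 0 else "rest",
        })
    if results:
        p_adj, rej = fdr_bh([r["p"] for r in results])
        for r, pa, rj in zip(results, p_adj, rej):
            r["p_fdr"] = float(pa)
            r["significant"] = bool(rj)
    return results
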