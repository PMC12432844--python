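"""Group correlated-components analysis (CCA) and time-resolved ISC.

The method finds channel weight vectors v that maximise the ratio of
between-subject to within-subject covariance, pooled over all subjects:

    maximise  v' Rb v / v' Rw v,
    Rw = sum_k R_kk,   Rb = sum_{k != l} R_kl,

where R_kl is the channel cross-covariance between subjects k and l. The
per-component inter-subject correlation is normalised as

    ISC_i = v_i' Rb v_i / ((N - 1) v_i' Rw v_i),

so that N identical subjects give ISC = 1. Time-resolved ISC applies the
weights fitted on the full recording to window-local covariances on a
5 s / 80 %-overlap grid; masked (outlier-zeroed) samples are excluded
pairwise throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .containers import GroupRecording, WindowGrid

__all__ = ["CCAModel", "ISCSeries", "pooled_covariances", "fit_cca",
           "isc_timecourse", "explained_covariance"]

_CHUNK = 65536  # samples per accumulation block for the masked covariance path


@dataclass
class CCAModel:
    """Fitted correlated-components model.

    ``weights`` columns are the component vectors v_i (highest ISC first);
    ``forward_models`` columns are the corresponding scalp topographies
    A = Rw W (W' Rw W)^-1.
    """

    weights: np.ndarray
    forward_models: np.ndarray
    Rw: np.ndarray
    Rb: np.ndarray
    isc: np.ndarray
    n_subjects: int

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclass
class ISCSeries:
    """Per-window ISC values for one component in one band.

    ``values`` are NaN where a window had fewer than 50 % unmasked samples
    for some subject.
    """

    component: int          # 1-based: C1, C2, ...
    band: str
    values: np.ndarray
    grid: WindowGrid
    start_times: np.ndarray = field(default=None)

    @property
    def name(self) -> str:
        return f"C{self.component}_{self.band}"


def _cov_arrays(X: np.ndarray, V: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (Rw, Rb) from a subjects x channels x time stack.

    V is a subjects x time validity matrix (None = all valid). Masked
    samples are excluded pairwise with pair-specific means.
    """
    n_sub, n_ch, n_t = X.shape
    if V is None or V.all():
        Xc = X - X.mean(axis=2, keepdims=True)
        auto = np.einsum("kct,kdt->cd", Xc, Xc) / (n_t - 1)
        S = Xc.sum(axis=0)
        total = (S @ S.T) / (n_t - 1)
        Rb = total - auto
        return auto, (Rb + Rb.T) / 2
    Vf = V.astype(float)
    Z = (X * Vf[:, None, :]).reshape(n_sub * n_ch, n_t)
    G = np.zeros((n_sub * n_ch, n_sub * n_ch))
    M = np.zeros((n_sub * n_ch, n_sub))
    cnt = np.zeros((n_sub, n_sub))
    for a in range(0, n_t, _CHUNK):
        Zb = Z[:, a:a + _CHUNK]
        Vb = Vf[:, a:a + _CHUNK]
        G += Zb @ Zb.T
        M += Zb @ Vb.T
        cnt += Vb @ Vb.T
    if cnt.min() < 2:
        raise ValueError("a subject pair has fewer than 2 jointly valid samples")
    Rw = np.zeros((n_ch, n_ch))
    Rb = np.zeros((n_ch, n_ch))
    for k in range(n_sub):
        for l in range(n_sub):
            n_kl = cnt[k, l]
            g = G[k * n_ch:(k + 1) * n_ch, l * n_ch:(l + 1) * n_ch]
            mu_k = M[k * n_ch:(k + 1) * n_ch, l] / n_kl
            mu_l = M[l * n_ch:(l + 1) * n_ch, k] / n_kl
            r = (g - n_kl * np.outer(mu_k, mu_l)) / (n_kl - 1)
            if k == l:
                Rw += r
            else:
                Rb += r
    return Rw, (Rb + Rb.T) / 2


def pooled_covariances(group: GroupRecording,
                       span: tuple[float, float] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within- (Rw) and between-subject (Rb) channel covariances.

    ``span`` restricts the computation to a [start, stop) interval in
    seconds. Masked samples are excluded pairwise; means are removed per
    span (per subject pair). Both matrices are symmetric.
    """
    if group.n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    X = group.data()
    V = group.validity()
    if span is not None:
        a = int(round(span[0] * group.sample_rate))
        b = int(round(span[1] * group.sample_rate))
        if not 0 <= a < b <= X.shape[2]:
            raise ValueError(f"span {span} outside recording")
        X, V = X[:, :, a:b], V[:, a:b]
    if V.sum(axis=1).min() < 2:
        raise ValueError("span has fewer than 2 valid samples for a subject")
    return _cov_arrays(X, V)


def fit_cca(Rw: np.ndarray, Rb: np.ndarray, n_subjects: int,
            n_components: int | None = None, reg: float = 0.1) -> CCAModel:
    """Solve the between/within generalized eigenproblem.

    Components solve ``Rb v = mu (Rw + reg * (tr(Rw)/D) I) v`` and are
    ordered by descending ISC. ``reg`` is shrinkage (diagonal loading)
    relative to the mean eigenvalue of Rw; 0 disables it. The sign of each
    component is fixed so its largest-magnitude weight is positive.
    """
    Rw = np.asarray(Rw, dtype=float)
    Rb = np.asarray(Rb, dtype=float)
    if not (np.isfinite(Rw).all() and np.isfinite(Rb).all()):
        raise ValueError("covariance matrices contain non-finite values")
    if reg < 0:
        raise ValueError("shrinkage must be non-negative")
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    d = Rw.shape[0]
    if np.linalg.eigvalsh(Rw).min() < -1e-8 * max(np.trace(Rw) / d, 1.0):
        raise ValueError("Rw is not positive semi-definite")
    Rw_reg = Rw + reg * (np.trace(Rw) / d) * np.eye(d)
    _, vecs = linalg.eigh(Rb, Rw_reg)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.einsum("ci,cd,di->i", vecs, Rb, vecs)
        den = (n_subjects - 1) * np.einsum("ci,cd,di->i", vecs, Rw, vecs)
        isc = num / den
    isc = np.where(np.isfinite(isc), isc, -np.inf)
    order = np.argsort(isc)[::-1]
    if n_components is not None:
        order = order[:n_components]
    W = vecs[:, order]
    isc = isc[order]
    # sign convention: largest-magnitude weight positive
    flip = W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])] < 0
    W[:, flip] *= -1
    gram = W.T @ Rw @ W
    A = Rw @ W @ np.linalg.pinv(gram)
    return CCAModel(weights=W, forward_models=A, Rw=Rw, Rb=Rb,
                    isc=isc, n_subjects=n_subjects)


def _winsum(x: np.ndarray, a: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Windowed sums along the last axis via a cumulative sum."""
    cs = np.cumsum(x, axis=-1, dtype=float)
    cs = np.concatenate([np.zeros(cs.shape[:-1] + (1,)), cs], axis=-1)
    return cs[..., e] - cs[..., a]


def _windowed_isc(y: np.ndarray, V: np.ndarray | None, starts_n: np.ndarray,
                  L: int, n_sub: int, min_valid: float) -> np.ndarray:
    """Windowed ISC of projected (per-subject scalar) series.

    Window-local covariances with per-window (and, under masking,
    per-pair) mean removal, assembled from cumulative sums so the cost is
    independent of the window overlap.
    """
    a, e = starts_n, starts_n + L
    if V is None or V.all():
        s1 = _winsum(y, a, e)                      # N x W sums
        s2 = _winsum(y * y, a, e)
        auto = (s2 - s1 * s1 / L) / (L - 1)        # within-subject window var
        s = y.sum(axis=0)
        t1 = _winsum(s, a, e)
        t2 = _winsum(s * s, a, e)
        total = (t2 - t1 * t1 / L) / (L - 1)
        num = total - auto.sum(axis=0)
        den = (n_sub - 1) * auto.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)
    Vf = V.astype(float)
    YV = y * Vf
    P = Vf[:, None, :] * Vf[None, :, :]            # N x N x T joint validity
    A = YV[:, None, :] * Vf[None, :, :]            # y_k over joint-valid
    C = YV[:, None, :] * YV[None, :, :]            # y_k y_l over joint-valid
    cnt = _winsum(P, a, e)
    sums = _winsum(A, a, e)
    cross = _winsum(C, a, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = (cross - sums * sums.transpose(1, 0, 2) / cnt) / (cnt - 1)
    cov = np.where(cnt >= 2, cov, np.nan)
    auto = np.einsum("aaw->aw", cov)
    num = np.nansum(cov, axis=(0, 1)) - np.nansum(auto, axis=0)
    den = (n_sub - 1) * np.nansum(auto, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num / den
    frac = _winsum(Vf, a, e) / L                   # N x W valid fraction
    return np.where(frac.min(axis=0) >= min_valid, vals, np.nan)


def isc_timecourse(group: GroupRecording, model: CCAModel,
                   grid: WindowGrid | None = None,
                   components: int = 1,
                   band: str = "",
                   min_valid: float = 0.5) -> list[ISCSeries]:
    """Windowed ISC with the model's fixed global weights.

    For each window w, ``ISC_i(w) = v_i' Rb(w) v_i / ((N-1) v_i' Rw(w) v_i)``
    with window-local covariances. Since the weights are fixed, each
    subject is first projected to a scalar series and windowed covariances
    are taken on the projections (mathematically identical, much cheaper).
    Windows where some subject has fewer than ``min_valid`` unmasked
    samples are NaN.
    """
    if grid is None:
        grid = WindowGrid()
    X = group.data()
    V = group.validity()
    rate = group.sample_rate
    slices = grid.sample_slices(group.duration, rate)
    if not slices:
        raise ValueError("no window fits within the recording span")
    starts_n = np.array([sl.start for sl in slices])
    L = slices[0].stop - slices[0].start
    if starts_n[-1] + L > X.shape[2]:
        raise ValueError("window extends outside recording span")
    out = []
    for comp in range(min(components, model.n_components)):
        v = model.weights[:, comp]
        y = np.einsum("c,kct->kt", v, X)
        vals = _windowed_isc(y, V, starts_n, L, group.n_subjects, min_valid)
        out.append(ISCSeries(component=comp + 1, band=band,
                             values=np.asarray(vals, dtype=float), grid=grid,
                             start_times=starts_n / rate))
    return out


def explained_covariance(model: CCAModel) -> np.ndarray:
    """Percentage of group covariance per component.

    ``pct_i = 100 * max(ISC_i, 0) / sum_j max(ISC_j, 0)`` over the full
    component set; requires at least one positive ISC.
    """
    if model.n_components < model.Rw.shape[0]:
        raise ValueError("explained covariance needs the full component set")
    pos = np.maximum(model.isc, 0.0)
    if pos.sum() <= 0:
        raise ValueError("all component ISCs are non-positive")
    return 100.0 * pos / pos.sum()
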