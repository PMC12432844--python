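"""Pairwise Granger causality from performance features to brain synchrony.

Each predictor is screened for stationarity with the Augmented
Dickey-Fuller test (constant-only regression, AIC lag selection) and first-
differenced if it fails. For each lag p in 1..15 the nested-autoregression
F-test compares the outcome regressed on its own p lags against the model
augmented with the predictor's p lags; BH-FDR corrects across the whole
predictor x lag grid. The scan is univariate by design: each feature is
tested on its own so different features may act at different timescales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .containers import FeatureSeries
from .surrogate import fdr_bh

__all__ = ["GrangerScan", "adf_test", "difference_series",
           "granger_pairwise", "granger_scan"]

logger = logging.getLogger(__name__)


@dataclass
class GrangerScan:
    """Lag-resolved pairwise Granger tests for one outcome series."""

    outcome: str
    predictors: list[str]
    lags: np.ndarray                       # tested lags (s at 1 Hz)
    F: np.ndarray                          # predictors x lags
    p: np.ndarray
    p_fdr: np.ndarray
    differenced: list[str] = field(default_factory=list)

    def significant(self, q: float = 0.05) -> np.ndarray:
        return self.p_fdr < q

    def min_significant_lag(self, predictor: str, q: float = 0.05) -> int | None:
        """Smallest lag at which a predictor is significant after FDR."""
        i = self.predictors.index(predictor)
        hits = np.flatnonzero(self.p_fdr[i] < q)
        return int(self.lags[hits[0]]) if hits.size else None

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, name in enumerate(self.predictors):
            for j, lag in enumerate(self.lags):
                rows.append({"predictor": name, "lag": int(lag),
                             "F": self.F[i, j], "p": self.p[i, j],
                             "p_fdr": self.p_fdr[i, j]})
        return pd.DataFrame(rows)


def adf_test(series: np.ndarray, alpha: float = 0.05
             ) -> tuple[float, float, bool]:
    """Augmented Dickey-Fuller unit-root test.

    Constant-only deterministic term, lag order chosen by AIC up to
    ``floor(12 * (n/100)^0.25)``; stationary iff p < alpha.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 50:
        raise ValueError("ADF screening needs at least 50 samples")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no unit-root test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p, *_ = adfuller(x, regression="c", autolag="AIC")
    return float(stat), float(p), bool(p < alpha)


def difference_series(series: np.ndarray) -> np.ndarray:
    """First difference (length n-1)."""
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("need at least 2 samples to difference")
    return np.diff(x)


def _lag_matrix(x: np.ndarray, p: int, n_obs: int) -> np.ndarray:
    """Columns x_{t-1} .. x_{t-p} for the last n_obs time points."""
    n = len(x)
    return np.column_stack([x[n - n_obs - k:n - k] for k in range(1, p + 1)])


def granger_pairwise(outcome: np.ndarray, predictor: np.ndarray,
                     lag: int) -> tuple[float, float]:
    """Nested-autoregression Granger test at a single lag order.

    Restricted model: outcome on its own lags 1..p (plus a constant);
    unrestricted adds the predictor's lags 1..p. Returns the SSR-based F
    statistic with (p, n - 2p - 1) degrees of freedom and its p-value.
    Collinear designs fall back to a tiny ridge with a warning.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    x = np.asarray(predictor, dtype=float).ravel()
    if len(y) != len(x):
        raise ValueError("series must have equal length")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    n_obs = len(y) - lag
    if n_obs <= 3 * lag + 10:
        raise ValueError("series too short for this lag order")
    yy = y[lag:]
    const = np.ones((n_obs, 1))
    Xr = np.hstack([const, _lag_matrix(y, lag, n_obs)])
    Xu = np.hstack([Xr, _lag_matrix(x, lag, n_obs)])

    def ssr(X):
        coef, res, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
        if rank < X.shape[1]:
            logger.warning("collinear lag design; ridge fallback")
            lam = 1e-8 * np.trace(X.T @ X) / X.shape[1]
            coef = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ yy)
        r = yy - X @ coef
        return float(r @ r)

    ssr_r, ssr_u = ssr(Xr), ssr(Xu)
    df2 = n_obs - 2 * lag - 1
    if ssr_u <= 0:
        return np.inf, 0.0
    F = ((ssr_r - ssr_u) / lag) / (ssr_u / df2)
    F = max(F, 0.0)
    return float(F), float(stats.f.sf(F, lag, df2))


def granger_scan(outcome: FeatureSeries | np.ndarray,
                 predictors: dict[str, FeatureSeries | np.ndarray],
                 max_lag: int = 15, q: float = 0.05,
                 auto_difference: bool = True,
                 screen: bool = True) -> GrangerScan:
    """Full predictor x lag grid of pairwise Granger tests with BH-FDR.

    Predictors failing the ADF screen are first-differenced when
    ``auto_difference`` is on, otherwise the scan refuses. The identical
    scan can be run against a surrogate outcome (e.g. ISC of circularly
    shifted data) as a negative control.
    """
    def values(s):
        return s.values if isinstance(s, FeatureSeries) else np.asarray(s, float)

    y = values(outcome)
    out_name = outcome.name if isinstance(outcome, FeatureSeries) else "outcome"
    names = list(predictors)
    lags = np.arange(1, max_lag + 1)
    if not names:
        return GrangerScan(outcome=out_name, predictors=[], lags=lags,
                           F=np.empty((0, max_lag)), p=np.empty((0, max_lag)),
                           p_fdr=np.empty((0, max_lag)))
    series = {}
    differenced = []
    for name in names:
        x = values(predictors[name])
        if len(x) != len(y):
            raise ValueError(f"predictor {name!r} length differs from outcome")
        if screen:
            _, _, ok = adf_test(x)
            if not ok:
                if not auto_difference:
                    raise ValueError(
                        f"predictor {name!r} failed the stationarity screen; "
                        "difference it or enable auto_difference")
                x = difference_series(x)
                differenced.append(name)
                logger.info("predictor %s differenced after failing ADF", name)
        series[name] = x
    F = np.empty((len(names), max_lag))
    P = np.empty((len(names), max_lag))
    for i, name in enumerate(names):
        x = series[name]
        yi = y[1:] if len(x) == len(y) - 1 else y
        for j, lag in enumerate(lags):
            F[i, j], P[i, j] = granger_pairwise(yi, x, int(lag))
    p_adj, _ = fdr_bh(P.ravel(), q=q)
    return GrangerScan(outcome=out_name, predictors=names, lags=lags,
                       F=F, p=P, p_fdr=p_adj.reshape(P.shape),
                       differenced=differenced)
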