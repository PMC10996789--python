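"""Robust correlation primitives for network construction.

The biweight midcorrelation (bicor) downweights observations far from the
median: with m = median(x) and MAD(x) = median(|x - m|),

    u_i = (x_i - m) / (9 * MAD(x))
    w_i = (1 - u_i^2)^2 * 1{|u_i| < 1}
    x~_i = (x_i - m) * w_i
    bicor(x, y) = sum(x~ y~) / (||x~|| * ||y~||)

Rows with MAD = 0 (no spread around the median) cannot be biweighted and
fall back to Pearson, which is logged.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def _biweight_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return row-normalised biweight vectors and a MAD==0 fallback mask.

    Each returned row has unit Euclidean norm; fallback rows are plain
    z-scored rows (Pearson behaviour).
    """
    x = np.asarray(x, float)
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    fallback = (mad[:, 0] == 0)

    centred = x - med
    with np.errstate(divide="ignore", invalid="ignore"):
        u = centred / (9.0 * mad)
    u[fallback] = 0.0
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    tilde = centred * w

    if fallback.any():
        mu = x[fallback].mean(axis=1, keepdims=True)
        tilde[fallback] = x[fallback] - mu

    norms = np.linalg.norm(tilde, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        bad = np.flatnonzero(zero)
        raise ValueError(
            f"constant row(s) with zero variance at index {bad.tolist()}"
        )
    return tilde / norms, fallback


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    tilde, _ = _biweight_rows(np.vstack([x, y]))
    return float(np.clip(tilde[0] @ tilde[1], -1.0, 1.0))


def bicor_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs bicor of the rows of ``values`` (proteins x samples).

    Returns a symmetric matrix with unit diagonal.  Requires >= 4 samples
    so the biweight has room to work.
    """
    values = np.asarray(values, float)
    if values.shape[1] < 4:
        raise ValueError("bicor_matrix requires at least 4 samples")
    tilde, fallback = _biweight_rows(values)
    if fallback.any():
        log.info("bicor: %d row(s) with MAD=0 fell back to Pearson",
                 int(fallback.sum()))
    c = tilde @ tilde.T
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def bicor_cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """bicor between rows of ``a`` and rows of ``b`` (same sample axis)."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("a and b must share the sample axis")
    ta, _ = _biweight_rows(a)
    tb, _ = _biweight_rows(b)
    return np.clip(ta @ tb.T, -1.0, 1.0)


def pearson_matrix(values: np.ndarray) -> np.ndarray:
    c = np.corrcoef(np.asarray(values, float))
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a correlation via the t approximation (df = n-2)."""
    r = np.asarray(r, float)
    if n < 3:
        raise ValueError("need at least 3 observations for a correlation test")
    r_ = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_ * np.sqrt((n - 2) / (1.0 - r_ ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r_) >= 1.0, 0.0, p)
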