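"""Dynamic Time Warping distances and the exponential DTW kernel.

The distance convention follows the common squiggle-comparison setup:
squared pointwise cost, step set {(1,0), (0,1), (1,1)}, both series
anchored at their endpoints, and a square root applied to the accumulated
cost at the end.  An optional Sakoe-Chiba band constrains the warping.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from numba import njit

__all__ = ["DtwConfig", "dtwd", "dtw_kernel", "pairwise_dtwd", "kernel_matrix"]

DEFAULT_GAMMA = 1.2  # kernel bandwidth used throughout the pipeline


@dataclasses.dataclass(frozen=True)
class DtwConfig:
    """Parameters of the DTW distance and kernel.

    window : half-width of the Sakoe-Chiba band in warping steps, or
        ``None`` for an unconstrained alignment.
    gamma : bandwidth of the exponential kernel exp(-gamma * d).
    """

    window: int | None = None
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.window is not None and self.window < 1:
            raise ValueError("window must be >= 1 when set")


@njit(cache=True)
def _dtw_sq(a, b, window):  # pragma: no cover - numba kernel
    n = a.shape[0]
    m = b.shape[0]
    if window < 0:
        w = n if n > m else m
    else:
        w = window
        d = n - m if n > m else m - n
        if w < d:
            w = d
    inf = np.inf
    prev = np.full(m + 1, inf)
    cur = np.full(m + 1, inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = inf
        lo = i - w
        if lo < 1:
            lo = 1
        hi = i + w
        if hi > m:
            hi = m
        for j in range(lo, hi + 1):
            c = a[i - 1] - b[j - 1]
            c = c * c
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _pairwise_sq(A, B, window, symmetric):  # pragma: no cover - numba kernel
    n = A.shape[0]
    m = B.shape[0]
    out = np.zeros((n, m))
    for i in range(n):
        start = i + 1 if symmetric else 0
        for j in range(start, m):
            out[i, j] = _dtw_sq(A[i], B[j], window)
    if symmetric:
        for i in range(n):
            for j in range(i):
                out[i, j] = out[j, i]
    return out


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("series must be a nonempty 1-D vector")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains NaN or infinite values")
    return arr


def dtwd(s1, s2, cfg: DtwConfig | None = None) -> float:
    """DTW distance between two series (>= 0, zero iff equal up to warping)."""
    cfg = cfg or DtwConfig()
    a = _as_series(s1)
    b = _as_series(s2)
    w = -1 if cfg.window is None else int(cfg.window)
    return math.sqrt(_dtw_sq(a, b, w))


def dtw_kernel(s1, s2, cfg: DtwConfig | None = None) -> float:
    """Exponential DTW kernel K(s1, s2) = exp(-gamma * DTWD(s1, s2))."""
    cfg = cfg or DtwConfig()
    return math.exp(-cfg.gamma * dtwd(s1, s2, cfg))


def _as_matrix(fps) -> np.ndarray:
    arr = np.asarray(fps, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] == 0:
        raise ValueError("expected a nonempty list of equal-length series")
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"non-finite value in series {bad[0]} position {bad[1]}")
    return arr


def pairwise_dtwd(A, B=None, cfg: DtwConfig | None = None) -> np.ndarray:
    """All-pairs DTW distance matrix.

    With ``B is None`` (or identical to ``A``) only the upper triangle is
    computed and mirrored, giving an exactly symmetric matrix with zero
    diagonal.  Entries are independent, so the result does not depend on
    evaluation order.
    """
    cfg = cfg or DtwConfig()
    a = _as_matrix(A)
    symmetric = B is None or B is A
    b = a if symmetric else _as_matrix(B)
    w = -1 if cfg.window is None else int(cfg.window)
    return np.sqrt(_pairwise_sq(a, b, w, symmetric))


def kernel_matrix(A, B=None, cfg: DtwConfig | None = None) -> np.ndarray:
    """exp(-gamma * D) for the pairwise distance matrix D."""
    cfg = cfg or DtwConfig()
    return np.exp(-cfg.gamma * pairwise_dtwd(A, B, cfg))
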