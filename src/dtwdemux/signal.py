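"""Raw-signal preprocessing: boundary detection, event segmentation and
barcode fingerprints.

A read's adapter span is located by finding the low-variance poly(A)
plateau and refining its onset with a two-piece Gaussian log-likelihood
changepoint.  The adapter is then over-segmented into events with a
windowed Welch t-statistic (~10% more segments than expected bases, so
missed events cannot truncate the barcode), normalized robustly, and the
last ``fingerprint_len`` (default 25) segment means — the temporal tail of
the adapter, where the barcode sits — form the read's fingerprint.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import RawRead

__all__ = [
    "SegmentationConfig",
    "Boundaries",
    "Fingerprint",
    "llr_changepoint",
    "detect_boundaries",
    "segment_adapter",
    "normalize",
    "extract_fingerprint",
    "FingerprintExtractor",
]

MAD_SCALE = 1.4826  # makes MAD a consistent sd estimator under normality
_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class SegmentationConfig:
    """Preprocessing parameters.

    ``expected_adapter_bases`` is the nominal adapter length in nucleotides;
    the adapter is cut into ``round(expected_adapter_bases * overseg_factor)``
    segments.  The poly(A) plateau is recognised as a run of low rolling
    variance at a level inside ``polyA_band`` (current units).
    """

    expected_adapter_bases: int = 50
    overseg_factor: float = 1.10
    tstat_window: int = 15
    min_seg_len: int = 3
    fingerprint_len: int = 25
    normalization: str = "median_mad"
    plateau_window: int = 200
    plateau_var_threshold: float | None = None  # absolute override; None = adaptive
    plateau_var_multiplier: float = 2.5
    noise_window: int = 25
    polyA_band: tuple[float, float] = (105.0, 145.0)
    min_plateau_samples: int = 400
    min_adapter_samples: int = 500
    refine_halfwidth: int = 300

    def __post_init__(self) -> None:
        if self.n_segments < self.fingerprint_len:
            raise ValueError("fingerprint_len must not exceed the segment count")
        if self.normalization not in ("median_mad", "zscore"):
            raise ValueError("normalization must be 'median_mad' or 'zscore'")

    @property
    def n_segments(self) -> int:
        return int(round(self.expected_adapter_bases * self.overseg_factor))


@dataclasses.dataclass(frozen=True)
class Boundaries:
    """0-based half-open sample intervals of the adapter and poly(A) spans."""

    adapter_start_idx: int
    adapter_end_idx: int
    polyA_end_idx: int
    qc_flags: frozenset[str] = frozenset()

    @property
    def ok(self) -> bool:
        return "no_polya" not in self.qc_flags and "too_short" not in self.qc_flags


@dataclasses.dataclass(frozen=True)
class Fingerprint:
    """Normalized last-``fingerprint_len`` segment means of the adapter."""

    values: np.ndarray | None
    read_id: str = ""
    qc_flags: frozenset[str] = frozenset()

    @property
    def ok(self) -> bool:
        return self.values is not None


def _rolling_mean_var(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean and (biased) variance over windows [i, i+w), i = 0..n-w."""
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    mean = s1 / w
    var = np.maximum(s2 / w - mean * mean, 0.0)
    return mean, var


def llr_changepoint(x: np.ndarray, min_seg: int = 2) -> int:
    """Split index t minimising the two-piece Gaussian log-likelihood cost
    ``n1*log(var(x[:t])) + n2*log(var(x[t:]))``.

    On a noiseless step the unique minimiser is exactly the step index;
    ties break to the lowest index.  Allowing a variance change (rather
    than a mean shift alone) is what separates a quiet plateau from a
    high-variance adapter.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2 * min_seg:
        raise ValueError("series too short for a changepoint")
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    t = np.arange(min_seg, n - min_seg + 1)
    n1 = t.astype(np.float64)
    n2 = n - n1
    v1 = np.maximum(c2[t] / n1 - (c1[t] / n1) ** 2, 0.0)
    v2 = np.maximum((c2[n] - c2[t]) / n2 - ((c1[n] - c1[t]) / n2) ** 2, 0.0)
    cost = n1 * np.log(v1 + _EPS) + n2 * np.log(v2 + _EPS)
    return int(t[np.argmin(cost)])


def detect_boundaries(read: RawRead, cfg: SegmentationConfig | None = None) -> Boundaries:
    """Locate the adapter / poly(A) / RNA-body boundaries of a raw read.

    Failure to find a plateau sets the ``no_polya`` flag instead of raising;
    such reads are routed to unclassified downstream.
    """
    cfg = cfg or SegmentationConfig()
    sig = read.signal
    w = cfg.plateau_window
    if sig.size < max(10 * cfg.tstat_window, 2 * w):
        return Boundaries(0, 0, 0, frozenset({"too_short"}))

    mean, var = _rolling_mean_var(sig, w)
    if cfg.plateau_var_threshold is not None:
        threshold = cfg.plateau_var_threshold
    else:
        # within-event measurement noise, estimated from the quietest small
        # windows; the poly(A) plateau has only that noise, while adapter and
        # RNA body add between-event level variance on top
        _, v_small = _rolling_mean_var(sig, cfg.noise_window)
        threshold = cfg.plateau_var_multiplier * float(np.quantile(v_small, 0.05)) + 1e-6
    lo, hi = cfg.polyA_band
    mask = (var < threshold) & (mean > lo) & (mean < hi)

    # first run of plateau-like windows long enough to span min_plateau_samples
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    plateau = None
    for s, e in zip(starts, ends):
        if (e - 1 + w) - s >= cfg.min_plateau_samples:
            plateau = (int(s), int(e - 1 + w))
            break
    if plateau is None:
        return Boundaries(0, 0, 0, frozenset({"no_polya"}))

    p_start, p_end = plateau
    left = max(0, p_start - cfg.refine_halfwidth)
    right = min(sig.size, p_start + w)
    adapter_end = left + llr_changepoint(sig[left:right])
    polyA_end = min(p_end, sig.size)

    flags = set()
    if adapter_end < cfg.min_adapter_samples:
        flags.add("short_adapter")
    return Boundaries(0, adapter_end, polyA_end, frozenset(flags))


def _welch_tstats(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Welch t between adjacent (clipped) windows at every interior position."""
    n = x.size
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    p = np.arange(2, n - 1)
    a_lo = np.maximum(p - w, 0)
    b_hi = np.minimum(p + w, n)
    na = (p - a_lo).astype(np.float64)
    nb = (b_hi - p).astype(np.float64)
    ma = (c1[p] - c1[a_lo]) / na
    mb = (c1[b_hi] - c1[p]) / nb
    va = np.maximum((c2[p] - c2[a_lo]) / na - ma * ma, 0.0)
    vb = np.maximum((c2[b_hi] - c2[p]) / nb - mb * mb, 0.0)
    t = np.abs(ma - mb) / np.sqrt(va / na + vb / nb + _EPS)
    return p, t


def segment_adapter(
    signal_slice: np.ndarray,
    n_segments: int,
    cfg: SegmentationConfig | None = None,
    return_edges: bool = False,
):
    """Partition a signal slice into ``n_segments`` events and return their means.

    Boundaries are the ``n_segments - 1`` highest Welch-t positions, taken
    greedily in descending t (ties to the lower index) subject to a
    ``min_seg_len`` spacing; if the spacing constraint exhausts the
    candidates the largest remaining gaps are split at their midpoints, so
    the result is always an exact partition.
    """
    cfg = cfg or SegmentationConfig()
    x = np.asarray(signal_slice, dtype=np.float64)
    n = x.size
    if n < n_segments * cfg.min_seg_len:
        raise ValueError(f"slice of {n} samples cannot hold {n_segments} segments of >= {cfg.min_seg_len}")
    if n_segments == 1:
        edges = np.array([0, n])
        return (np.array([x.mean()]), edges) if return_edges else np.array([x.mean()])

    pos, t = _welch_tstats(x, cfg.tstat_window)
    order = np.lexsort((pos, -t))  # descending t, ties to lower index
    chosen: list[int] = []
    msl = cfg.min_seg_len
    for idx in order:
        p = int(pos[idx])
        if p < msl or p > n - msl:
            continue
        if all(abs(p - q) >= msl for q in chosen):
            chosen.append(p)
            if len(chosen) == n_segments - 1:
                break
    while len(chosen) < n_segments - 1:  # deterministic fill of largest gaps
        bounds = sorted([0, n] + chosen)
        gaps = [(bounds[i + 1] - bounds[i], bounds[i]) for i in range(len(bounds) - 1)]
        length, start = max(gaps, key=lambda g: (g[0], -g[1]))
        if length < 2 * msl:
            # greedy spacing stranded the layout (short slices): even partition
            chosen = np.linspace(0, n, n_segments + 1)[1:-1].astype(int).tolist()
            break
        chosen.append(start + length // 2)
    edges = np.concatenate([[0], np.sort(np.asarray(chosen)), [n]])
    sums = np.add.reduceat(x, edges[:-1])
    means = sums / np.diff(edges)
    return (means, edges) if return_edges else means


def normalize(values: np.ndarray, method: str = "median_mad") -> np.ndarray:
    """Robust (median/MAD) or classical z-score normalization.

    median/MAD uses the 1.4826 consistency factor; a zero MAD falls back to
    z-scoring, and a zero sd returns all zeros.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    scale_floor = 1e-12 * max(1.0, float(np.max(np.abs(x))))  # constant up to float error
    if method == "median_mad":
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > scale_floor:
            return (x - med) / (mad * MAD_SCALE)
        method = "zscore"
    if method != "zscore":
        raise ValueError(f"unknown normalization {method!r}")
    sd = x.std()
    if sd <= scale_floor:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def extract_fingerprint(read: RawRead, cfg: SegmentationConfig | None = None) -> Fingerprint:
    """Full preprocessing of one read: boundaries -> segments -> normalize -> last 25.

    Normalization runs over all ``n_segments`` before trimming, so the
    fingerprint keeps its scale relative to the whole adapter.  Boundary
    failures yield a flagged, valueless fingerprint rather than an error.
    """
    cfg = cfg or SegmentationConfig()
    b = detect_boundaries(read, cfg)
    if not b.ok:
        return Fingerprint(None, read.read_id, b.qc_flags)
    adapter = read.signal[b.adapter_start_idx : b.adapter_end_idx]
    if adapter.size < cfg.n_segments * cfg.min_seg_len:
        return Fingerprint(None, read.read_id, b.qc_flags | {"short_adapter"})
    means = segment_adapter(adapter, cfg.n_segments, cfg)
    values = normalize(means, cfg.normalization)[-cfg.fingerprint_len :]
    return Fingerprint(values, read.read_id, b.qc_flags)


class FingerprintExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping raw reads to fingerprint rows.

    ``transform`` returns an ``(n_reads, fingerprint_len)`` float array with
    NaN rows for QC failures; per-read flags are kept in ``qc_flags_``.
    """

    def __init__(self, cfg: SegmentationConfig | None = None):
        self.cfg = cfg

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self.cfg or SegmentationConfig()
        out = np.full((len(X), cfg.fingerprint_len), np.nan)
        flags = []
        for i, read in enumerate(X):
            fp = extract_fingerprint(read, cfg)
            flags.append(fp.qc_flags)
            if fp.ok:
                out[i] = fp.values
        self.qc_flags_ = flags
        return out
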