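"""Training-set construction: noise-instance mining and diversity-stratified
subsampling.

Noise instances are reads whose median DTW distance to reads of *other*
barcode classes is an outlier (large robust Z-score): a read that is far
from everything is more likely a signal artefact than a clean barcode.
Per-barcode training sets then combine greedy maximal-diversity, greedy
minimal-diversity and random strata (80 + 80 + 240 by default) so a small
set still covers the whole signal distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dtw import DtwConfig, pairwise_dtwd
from .simulate import NOISE_LABEL

__all__ = [
    "LabeledFingerprintSet",
    "robust_zscore",
    "select_noise_instances",
    "diversity_split",
]

DEFAULT_STRATA = {"max_div": 80, "min_div": 80, "random": 240}


@dataclasses.dataclass
class LabeledFingerprintSet:
    """Parallel fingerprints / labels (barcode label or NOISE), optionally
    tagged with a replicate stratum per read."""

    fingerprints: np.ndarray  # (n, fingerprint_len)
    labels: np.ndarray  # (n,) str
    read_ids: np.ndarray | None = None
    replicate_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if len(self.fingerprints) != len(self.labels):
            raise ValueError("fingerprints and labels must be parallel")
        if self.read_ids is None:
            self.read_ids = np.array([f"read_{i:06d}" for i in range(len(self.labels))])

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, indices) -> "LabeledFingerprintSet":
        idx = np.asarray(indices)
        return LabeledFingerprintSet(
            self.fingerprints[idx],
            self.labels[idx],
            self.read_ids[idx],
            None if self.replicate_id is None else np.asarray(self.replicate_id)[idx],
        )


def robust_zscore(X) -> np.ndarray:
    """(X - median) / MAD with the all-zero convention when MAD = 0."""
    x = np.asarray(X, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in X")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    return (x - med) / mad


def median_interclass_distance(
    data: LabeledFingerprintSet,
    cap: int = 200,
    seed: int = 0,
    dtw_cfg: DtwConfig | None = None,
) -> np.ndarray:
    """Per read: median DTWD to (a capped random sample of) other-class reads."""
    labels = data.labels
    classes = [c for c in np.unique(labels) if c != NOISE_LABEL]
    if len(classes) < 2:
        raise ValueError("need at least 2 barcode classes")
    rng = np.random.default_rng(seed)
    out = np.empty(len(data))
    for cls in np.unique(labels):
        own = np.flatnonzero(labels == cls)
        other = np.flatnonzero((labels != cls) & (labels != NOISE_LABEL))
        if cls == NOISE_LABEL:  # score noise-labeled reads against everything else
            other = np.flatnonzero(labels != NOISE_LABEL)
        if other.size > cap:
            other = rng.choice(other, size=cap, replace=False)
        D = pairwise_dtwd(data.fingerprints[own], data.fingerprints[other], dtw_cfg)
        out[own] = np.median(D, axis=1)
    return out


def select_noise_instances(
    data: LabeledFingerprintSet,
    n_noise: int = 400,
    z_cutoff: float = 3.5,
    cap: int = 200,
    seed: int = 0,
    dtw_cfg: DtwConfig | None = None,
) -> np.ndarray:
    """Indices of up to ``n_noise`` outlier reads by robust Z-score of the
    median inter-class distance (descending score, only scores > z_cutoff)."""
    if n_noise > len(data):
        raise ValueError("n_noise exceeds dataset size")
    X = median_interclass_distance(data, cap, seed, dtw_cfg)
    z = robust_zscore(X)
    order = np.lexsort((np.arange(len(z)), -z))
    picked = [int(i) for i in order[:n_noise] if z[i] > z_cutoff]
    return np.asarray(picked, dtype=np.int64)


def _greedy_diverse(D: np.ndarray, k: int, maximize: bool) -> list[int]:
    """Greedy sum-objective diversity selection on a local distance matrix."""
    n = D.shape[0]
    if k >= n:
        return list(range(n))
    masked = D.copy()
    np.fill_diagonal(masked, -np.inf if maximize else np.inf)
    flat = np.argmax(masked) if maximize else np.argmin(masked)
    i, j = np.unravel_index(flat, D.shape)
    sel = sorted({int(i), int(j)})
    while len(sel) < k:
        rest = np.setdiff1d(np.arange(n), sel)
        sums = D[np.ix_(rest, sel)].sum(axis=1)
        pick = np.argmax(sums) if maximize else np.argmin(sums)
        sel.append(int(rest[pick]))
    return sel


def diversity_split(
    pool: LabeledFingerprintSet,
    per_class: dict[str, int] | None = None,
    seed: int = 0,
    dtw_cfg: DtwConfig | None = None,
) -> tuple[LabeledFingerprintSet, dict[str, dict[str, list[str]]]]:
    """Per-barcode training selection: greedy max-diversity, then greedy
    min-diversity from the remainder, then a random completion (stratified
    across replicate groups when present).

    Returns the selected set and a manifest mapping class -> stratum ->
    selected read_ids.
    """
    per_class = per_class or dict(DEFAULT_STRATA)
    need = sum(per_class.values())
    rng = np.random.default_rng(seed)
    classes = [c for c in np.unique(pool.labels) if c != NOISE_LABEL]
    keep: list[int] = []
    manifest: dict[str, dict[str, list[str]]] = {}
    for cls in classes:
        own = np.flatnonzero(pool.labels == cls)
        if own.size < need:
            raise ValueError(f"class {cls!r} has {own.size} reads, needs >= {need}")
        D = pairwise_dtwd(pool.fingerprints[own], cfg=dtw_cfg)
        max_sel = _greedy_diverse(D, per_class.get("max_div", 0), maximize=True)
        remaining = np.setdiff1d(np.arange(own.size), max_sel)
        Dr = D[np.ix_(remaining, remaining)]
        min_sel = remaining[_greedy_diverse(Dr, per_class.get("min_div", 0), maximize=False)]
        left = np.setdiff1d(np.arange(own.size), np.concatenate([max_sel, min_sel]))
        n_rand = per_class.get("random", 0)
        rand_sel = _stratified_sample(left, n_rand, pool, own, rng)
        manifest[str(cls)] = {
            "max_div": [str(r) for r in pool.read_ids[own[max_sel]]],
            "min_div": [str(r) for r in pool.read_ids[own[min_sel]]],
            "random": [str(r) for r in pool.read_ids[own[rand_sel]]],
        }
        keep.extend(own[np.concatenate([max_sel, min_sel, rand_sel]).astype(np.int64)])
    return pool.subset(np.asarray(keep, dtype=np.int64)), manifest


def _stratified_sample(local_idx, n, pool, own, rng) -> np.ndarray:
    if n == 0 or local_idx.size == 0:
        return np.empty(0, dtype=np.int64)
    if pool.replicate_id is None:
        return rng.choice(local_idx, size=n, replace=False)
    reps = np.asarray(pool.replicate_id)[own[local_idx]]
    groups = np.unique(reps)
    quota = {g: n // len(groups) for g in groups}
    for g in groups[: n % len(groups)]:
        quota[g] += 1
    out: list[int] = []
    short = 0
    for g in groups:
        members = local_idx[reps == g]
        take = min(quota[g], members.size)
        short += quota[g] - take
        out.extend(rng.choice(members, size=take, replace=False).tolist())
    if short:  # refill from whatever is left, keeping the total exact
        left = np.setdiff1d(local_idx, out)
        out.extend(rng.choice(left, size=short, replace=False).tolist())
    return np.asarray(sorted(out), dtype=np.int64)
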