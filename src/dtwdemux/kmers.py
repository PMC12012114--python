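"""k-mer current-level models.

A k-mer model maps each DNA k-mer to the mean ionic current observed while
that k-mer occupies the pore.  It drives both signal prediction at barcode
design time and squiggle simulation.  RNA translocates 3'->5', and no pore
model exists for DNA read in that direction, so design restricts itself to
k-mers whose predicted level is robust to reading direction (the level of
the k-mer and of its reversal agree within a tolerance).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "KmerModel",
    "load_kmer_model",
    "write_kmer_model",
    "synthetic_kmer_model",
    "predict_levels",
    "bidirectional_kmers",
]

_ALPHABET = "ACGT"


@dataclasses.dataclass(frozen=True)
class KmerModel:
    k: int
    levels: dict[str, float]
    level_sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for kmer, level in self.levels.items():
            if len(kmer) != self.k or any(c not in _ALPHABET for c in kmer):
                raise ValueError(f"invalid {self.k}-mer key: {kmer!r}")
            if not np.isfinite(level):
                raise ValueError(f"non-finite level for {kmer}")

    def __len__(self) -> int:
        return len(self.levels)


def load_kmer_model(path: str | Path) -> KmerModel:
    """Read an ONT-style k-mer model TSV (columns kmer, level_mean[, level_stdv])."""
    path = Path(path)
    levels: dict[str, float] = {}
    sds: dict[str, float] = {}
    k = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            kmer_col = header.index("kmer")
            mean_col = header.index("level_mean")
        except ValueError as exc:
            raise ValueError(f"{path}: header must contain 'kmer' and 'level_mean'") from exc
        sd_col = header.index("level_stdv") if "level_stdv" in header else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            kmer = fields[kmer_col]
            if k is None:
                k = len(kmer)
            if len(kmer) != k:
                raise ValueError(f"{path}:{lineno}: {kmer!r} is not a {k}-mer")
            try:
                levels[kmer] = float(fields[mean_col])
                if sd_col is not None:
                    sds[kmer] = float(fields[sd_col])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric level") from exc
    if not levels:
        raise ValueError(f"{path}: no k-mer rows")
    return KmerModel(k=k, levels=levels, level_sd=sds or None)


def write_kmer_model(model: KmerModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        cols = ["kmer", "level_mean"] + (["level_stdv"] if model.level_sd else [])
        fh.write("\t".join(cols) + "\n")
        for kmer in sorted(model.levels):
            row = [kmer, f"{model.levels[kmer]:.6f}"]
            if model.level_sd:
                row.append(f"{model.level_sd[kmer]:.6f}")
            fh.write("\t".join(row) + "\n")


def synthetic_kmer_model(k: int = 5, seed: int = 20177, low: float = 60.0, high: float = 130.0) -> KmerModel:
    """Deterministic synthetic pore model: one level per k-mer, uniform in [low, high].

    Stands in for a measured pore table so the package needs no downloads;
    the level range matches a typical RNA002 current scale (pA).
    """
    rng = np.random.default_rng(seed)
    kmers = [""]
    for _ in range(k):
        kmers = [p + c for p in kmers for c in _ALPHABET]
    values = rng.uniform(low, high, size=len(kmers))
    return KmerModel(k=k, levels=dict(zip(kmers, values.tolist())))


def predict_levels(seq: str, model: KmerModel) -> np.ndarray:
    """Expected level sequence of ``seq``, read in translocation (3'->5') order.

    The caller supplies the already-oriented string; position i carries the
    level of ``seq[i:i+k]``.  Length is ``len(seq) - k + 1``.
    """
    k = model.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    out = np.empty(len(seq) - k + 1)
    for i in range(out.size):
        kmer = seq[i : i + k]
        try:
            out[i] = model.levels[kmer]
        except KeyError:
            raise KeyError(f"k-mer {kmer!r} missing from model") from None
    return out


def bidirectional_kmers(model: KmerModel, tol: float | None = None) -> set[str]:
    """k-mers whose level matches that of their reversal within ``tol``.

    ``tol`` defaults to half the inter-quartile range of the model levels.
    The filter is monotone in tol and always keeps reversal palindromes.
    """
    if tol is None:
        q75, q25 = np.percentile(list(model.levels.values()), [75, 25])
        tol = 0.5 * (q75 - q25)
    if tol < 0:
        raise ValueError("tol must be >= 0")
    keep = set()
    for kmer, level in model.levels.items():
        rev = kmer[::-1]
        other = model.levels.get(rev)
        if other is not None and abs(level - other) <= tol:
            keep.add(kmer)
    return keep
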