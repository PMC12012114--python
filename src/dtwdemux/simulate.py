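"""Synthetic direct-RNA-seq squiggle simulator.

Each simulated read has the anatomy of a real dRNA-seq raw trace, in
sequencing order: the DNA adapter signal (whose temporal tail encodes the
barcode), a long near-constant poly(A) plateau, and an RNA body modelled as
a slow random walk over current levels.  Per-base dwell times are drawn
from a negative binomial, and Gaussian measurement noise is added to every
sample.  Corrupted "noise" reads emulate stalled adapters, truncated
adapters and missing poly(A) tails.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .kmers import KmerModel, predict_levels

__all__ = ["SimConfig", "ReadTruth", "RawRead", "simulate_read", "simulate_dataset", "NOISE_LABEL"]

NOISE_LABEL = "NOISE"
_LEADER_SEED = 7_314_159  # the adapter leader is shared by all barcodes
CORRUPTION_OPS = ("plateau", "truncate", "no_polya")


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulator.

    Defaults emulate an RNA002-like pore: 3012 Hz sampling at 70 nt/s
    translocation (mean dwell ~43 samples per base), within-event noise of
    ~2.5 pA on a 60-130 pA level scale, and a high steady poly(A) level.
    ``rna004()`` gives the faster-chemistry preset.
    """

    sample_rate: float = 3012.0
    translocation_speed: float = 70.0
    dwell_dispersion: float = 0.25
    noise_sd: float = 2.5
    polyA_level: float = 125.0
    polyA_len_nt: int = 150
    adapter_seq_len: int = 50
    barcode_len: int = 18
    rna_body_len_nt: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dwell_mean <= 1.0:
            raise ValueError("mean dwell sample_rate/translocation_speed must exceed 1 sample")
        if self.dwell_dispersion < 0 or self.noise_sd < 0:
            raise ValueError("dwell_dispersion and noise_sd must be >= 0")
        for name in ("polyA_len_nt", "adapter_seq_len", "barcode_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rna_body_len_nt < 0:
            raise ValueError("rna_body_len_nt must be >= 0")
        if self.barcode_len >= self.adapter_seq_len:
            raise ValueError("adapter_seq_len must exceed barcode_len")

    @property
    def dwell_mean(self) -> float:
        return self.sample_rate / self.translocation_speed

    @classmethod
    def rna004(cls, **kw) -> "SimConfig":
        kw.setdefault("sample_rate", 4000.0)
        kw.setdefault("translocation_speed", 130.0)
        return cls(**kw)


@dataclasses.dataclass
class ReadTruth:
    barcode_label: str
    adapter_end_idx: int
    polyA_end_idx: int
    source_barcode: str | None = None
    adapter_levels: np.ndarray | None = None
    adapter_dwells: np.ndarray | None = None


@dataclasses.dataclass
class RawRead:
    read_id: str
    signal: np.ndarray
    sample_rate: float
    truth: ReadTruth | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a nonempty 1-D vector")
        t = self.truth
        if t is not None and not (0 <= t.adapter_end_idx <= t.polyA_end_idx <= self.signal.size):
            raise ValueError("inconsistent truth boundary indices")


def _leader_seq(cfg: SimConfig) -> str:
    rng = np.random.default_rng(_LEADER_SEED + cfg.adapter_seq_len)
    n = cfg.adapter_seq_len - cfg.barcode_len
    return "".join(rng.choice(list("ACGT"), size=n))


def _dwells(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mu = cfg.dwell_mean
    d = cfg.dwell_dispersion
    if d == 0:
        return np.full(n, int(round(mu)), dtype=np.int64)
    # NB2: var = mu + d*mu^2; numpy parameterization n=1/d, p=n/(n+mu)
    size = 1.0 / d
    draws = rng.negative_binomial(size, size / (size + mu), size=n)
    return np.maximum(draws, 1).astype(np.int64)


def _body_levels(n: int, rng: np.random.Generator) -> np.ndarray:
    # random walk with reflecting boundaries: a hard clip would create long
    # constant runs that mimic a poly(A) plateau
    steps = rng.normal(0.0, 8.0, size=n)
    walk = 95.0 + np.cumsum(steps)
    lo, hi = 60.0, 130.0
    period = 2.0 * (hi - lo)
    folded = np.mod(walk - lo, period)
    return lo + np.where(folded > hi - lo, period - folded, folded)


def simulate_read(
    barcode_seq: str,
    kmer_model: KmerModel,
    cfg: SimConfig,
    read_id: str = "read_0",
    rng: np.random.Generator | None = None,
    label: str | None = None,
) -> RawRead:
    """Simulate one read whose adapter 3' end encodes ``barcode_seq`` (3'->5')."""
    if any(c not in "ACGT" for c in barcode_seq):
        raise ValueError("barcode_seq must be over {A,C,G,T}")
    if len(barcode_seq) != cfg.barcode_len:
        raise ValueError(f"barcode_seq length {len(barcode_seq)} != cfg.barcode_len {cfg.barcode_len}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng

    adapter_seq = _leader_seq(cfg) + barcode_seq
    levels = predict_levels(adapter_seq, kmer_model)
    dwells = _dwells(levels.size, cfg, rng)
    adapter = np.repeat(levels, dwells)

    polyA_dwells = _dwells(cfg.polyA_len_nt, cfg, rng)
    polyA = np.full(int(polyA_dwells.sum()), cfg.polyA_level)

    if cfg.rna_body_len_nt > 0:
        body_levels = _body_levels(cfg.rna_body_len_nt, rng)
        body = np.repeat(body_levels, _dwells(cfg.rna_body_len_nt, cfg, rng))
    else:
        body = np.empty(0)

    signal = np.concatenate([adapter, polyA, body])
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.size)

    truth = ReadTruth(
        barcode_label=label if label is not None else barcode_seq,
        adapter_end_idx=adapter.size,
        polyA_end_idx=adapter.size + polyA.size,
        adapter_levels=levels,
        adapter_dwells=dwells,
    )
    return RawRead(read_id=read_id, signal=signal, sample_rate=cfg.sample_rate, truth=truth)


def _corrupt(read: RawRead, op: str, cfg: SimConfig, rng: np.random.Generator) -> RawRead:
    """Apply one signal-irregularity operator; the result is labeled NOISE."""
    t = read.truth
    sig = read.signal
    if op == "plateau":
        # stalled/blocked pore: the pore stalls partway through the adapter
        # and at least half of the adapter-tail signal (the barcode span) is
        # replaced by a suppressed-current plateau; blockage pulls the
        # current below the open-adapter level range
        frac = rng.uniform(0.5, 0.9)
        start = int(t.adapter_end_idx * (1.0 - frac))
        level = rng.uniform(40.0, 65.0)
        sig = sig.copy()
        sig[start : t.adapter_end_idx] = level + rng.normal(
            0.0, cfg.noise_sd, size=t.adapter_end_idx - start
        )
        a_end, p_end = t.adapter_end_idx, t.polyA_end_idx
    elif op == "truncate":  # >= 50% of the adapter is missing
        cut = int(t.adapter_end_idx * rng.uniform(0.5, 0.9))
        sig = sig[cut:]
        a_end, p_end = t.adapter_end_idx - cut, t.polyA_end_idx - cut
    elif op == "no_polya":  # DNA/RNA boundary unmarked
        sig = np.concatenate([sig[: t.adapter_end_idx], sig[t.polyA_end_idx :]])
        a_end = p_end = t.adapter_end_idx
    else:
        raise ValueError(f"unknown corruption op {op!r}")
    truth = ReadTruth(
        barcode_label=NOISE_LABEL,
        adapter_end_idx=a_end,
        polyA_end_idx=p_end,
        source_barcode=t.barcode_label,
    )
    return RawRead(read_id=read.read_id, signal=sig, sample_rate=read.sample_rate, truth=truth)


def simulate_dataset(
    barcode_set: dict[str, str] | list[str],
    n_per_barcode: int | dict[str, int],
    noise_fraction: float = 0.0,
    cfg: SimConfig | None = None,
    kmer_model: KmerModel | None = None,
    corruption_ops: tuple[str, ...] = CORRUPTION_OPS,
) -> list[RawRead]:
    """Balanced labeled reads plus a ``noise_fraction`` share of corrupted reads.

    ``noise_fraction`` is the NOISE share of the *total* dataset, so the
    number of noise reads is ``round(f/(1-f) * n_barcode_reads)``.
    ``barcode_set`` maps label -> sequence (a list gets labels BC01, BC02, ...);
    ``n_per_barcode`` may be a per-label mapping for skewed mixtures.
    """
    from .kmers import synthetic_kmer_model

    if not barcode_set:
        raise ValueError("barcode_set must be nonempty")
    if not 0 <= noise_fraction < 1:
        raise ValueError("noise_fraction must be in [0, 1)")
    cfg = cfg or SimConfig()
    kmer_model = kmer_model or synthetic_kmer_model()
    if not isinstance(barcode_set, dict):
        barcode_set = {f"BC{i + 1:02d}": seq for i, seq in enumerate(barcode_set)}
    if not isinstance(n_per_barcode, dict):
        n_per_barcode = {label: n_per_barcode for label in barcode_set}
    if any(n < 1 for n in n_per_barcode.values()):
        raise ValueError("n_per_barcode must be >= 1")

    rng = np.random.default_rng(cfg.seed)
    reads: list[RawRead] = []
    serial = 0
    for label, seq in barcode_set.items():
        for _ in range(n_per_barcode[label]):
            reads.append(simulate_read(seq, kmer_model, cfg, f"read_{serial:06d}", rng, label=label))
            serial += 1
    n_noise = int(round(noise_fraction / (1.0 - noise_fraction) * len(reads)))
    labels = list(barcode_set)
    for _ in range(n_noise):
        label = labels[int(rng.integers(len(labels)))]
        clean = simulate_read(barcode_set[label], kmer_model, cfg, f"read_{serial:06d}", rng, label=label)
        op = corruption_ops[int(rng.integers(len(corruption_ops)))]
        reads.append(_corrupt(clean, op, cfg, rng))
        serial += 1
    return reads
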