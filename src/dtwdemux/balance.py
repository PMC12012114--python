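"""Barcode-balancing adaptive sampling, simulated.

Reads are streamed to channel caches in fixed-duration chunks (default
100 ms, ~300 samples at 3012 Hz).  As soon as the poly(A) onset is seen in
the accumulated signal, the adapter span is fingerprinted and classified;
a dynamic rule then rejects reads of over-represented barcodes (tally
above ``slack`` x the mean tally), which frees the channel after only the
consumed samples plus a rejection penalty.  Adapter-only reads — adapters
that never ligated to an RNA molecule — are corrected against the
sequencer output so they do not skew the tracked distribution.  Imbalance
is scored with the Gini coefficient of per-barcode counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .classify import STATUS_CLASSIFIED, DtwKernelSvmClassifier
from .signal import SegmentationConfig, extract_fingerprint
from .simulate import NOISE_LABEL, RawRead

__all__ = [
    "StreamChunk",
    "stream_reads",
    "LiveResult",
    "live_classify",
    "BalancerState",
    "decide",
    "run_balancing_experiment",
    "gini",
]

ACCEPT = "accept"
REJECT = "reject"
NO_DECISION = "no_decision"


def gini(counts) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 mean); 0 = balanced."""
    x = np.asarray(counts, dtype=np.float64)
    if x.size == 0 or np.any(x < 0) or x.sum() == 0:
        raise ValueError("counts must be non-negative with a positive sum")
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff / (2.0 * x.size**2 * x.mean()))


@dataclasses.dataclass(frozen=True)
class StreamChunk:
    channel: int
    read_id: str
    read_serial: int
    samples: np.ndarray
    is_read_start: bool


def stream_reads(dataset: list[RawRead], chunk_ms: float = 100.0, n_channels: int = 1,
                 seed: int = 0):
    """Yield reads' signals as fixed-duration chunks, interleaved round-robin
    across channels; within a read, chunks arrive in temporal order."""
    if not dataset:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    queues: list[list[int]] = [[] for _ in range(n_channels)]
    for pos, read_idx in enumerate(order):
        queues[pos % n_channels].append(int(read_idx))

    cursors = [(0, 0) for _ in range(n_channels)]  # (queue position, sample offset)
    active = [True] * n_channels
    while any(active):
        for ch in range(n_channels):
            if not active[ch]:
                continue
            qpos, offset = cursors[ch]
            if qpos >= len(queues[ch]):
                active[ch] = False
                continue
            read = dataset[queues[ch][qpos]]
            chunk_len = int(round(chunk_ms * read.sample_rate / 1000.0))
            samples = read.signal[offset : offset + chunk_len]
            yield StreamChunk(ch, read.read_id, queues[ch][qpos], samples, offset == 0)
            offset += len(samples)
            cursors[ch] = (qpos + 1, 0) if offset >= read.signal.size else (qpos, offset)


@dataclasses.dataclass
class LiveResult:
    read_id: str
    label: str | None
    confidence: float
    status: str
    samples_consumed: int


def live_classify(
    chunks,
    model: DtwKernelSvmClassifier,
    seg_cfg: SegmentationConfig | None = None,
    max_samples: int = 40000,
    conf_cutoff: float = 0.0,
) -> LiveResult:
    """Accumulate one read's chunks until the poly(A) onset appears, then
    fingerprint the adapter span and classify.

    The poly(A) detector only needs to *confirm* a plateau, so it runs with
    a reduced minimum plateau length; ``samples_consumed`` (the decision
    latency proxy) is the number of samples buffered when the decision was
    made.  No onset within ``max_samples`` gives ``no_decision``.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    live_cfg = dataclasses.replace(
        seg_cfg, min_plateau_samples=min(seg_cfg.min_plateau_samples, 2 * seg_cfg.plateau_window)
    )
    buffer = np.empty(0)
    read_id = ""
    for chunk in chunks:
        read_id = chunk.read_id
        buffer = np.concatenate([buffer, chunk.samples])
        if buffer.size < 2 * live_cfg.plateau_window:
            continue
        # sample_rate is irrelevant to boundary detection on a buffered span
        fp = extract_fingerprint(RawRead(read_id, buffer, 1.0, None), live_cfg)
        if fp.ok:
            row = model.classify(fp.values, conf_cutoff=conf_cutoff).iloc[0]
            return LiveResult(read_id, str(row["predicted_label"]), float(row["confidence"]),
                              str(row["status"]), int(buffer.size))
        if "no_polya" not in fp.qc_flags:  # boundary found but fingerprint failed
            return LiveResult(read_id, None, float("nan"), "qc_fail", int(buffer.size))
        if buffer.size >= max_samples:
            break
    return LiveResult(read_id, None, float("nan"), NO_DECISION, int(buffer.size))


@dataclasses.dataclass
class BalancerState:
    """Live per-barcode tallies and the dynamic rejection rule.

    A barcode is rejected when its tally on the balancing metric exceeds
    ``slack`` times the mean tally over barcodes already seen; the
    threshold is recomputed at every decision, so it tracks the evolving
    distribution.  No barcode is rejected before its tally reaches
    ``min_count`` — with only a handful of observations the empirical
    distribution is noise and early rejections would hit rare barcodes.
    """

    barcodes: list[str]
    balance_metric: str = "adapter_count"
    slack: float = 1.2
    min_count: int = 10
    adapters: dict[str, int] = dataclasses.field(default_factory=dict)
    reads: dict[str, int] = dataclasses.field(default_factory=dict)
    bases: dict[str, int] = dataclasses.field(default_factory=dict)
    decisions: list[tuple[str, str, str]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.balance_metric not in ("adapter_count", "read_count", "base_count"):
            raise ValueError(f"unknown balance metric {self.balance_metric!r}")
        for b in self.barcodes:
            self.adapters.setdefault(b, 0)
            self.reads.setdefault(b, 0)
            self.bases.setdefault(b, 0)

    def _tallies(self) -> dict[str, int]:
        return {"adapter_count": self.adapters, "read_count": self.reads, "base_count": self.bases}[
            self.balance_metric
        ]


def decide(state: BalancerState, predicted_barcode: str | None, confidence: float,
           conf_cutoff: float = 0.0, status: str = STATUS_CLASSIFIED) -> str:
    """Accept/reject decision for one classified adapter.

    Reads without a confident barcode identity (noise, QC failure, below
    the cutoff) are accepted: a sample must never be discarded on an
    unknown identity.  The tally update happens after the decision.
    """
    if status != STATUS_CLASSIFIED or predicted_barcode is None or (
        not np.isnan(confidence) and confidence < conf_cutoff
    ):
        state.decisions.append((predicted_barcode or "", str(status), ACCEPT))
        return ACCEPT
    if predicted_barcode not in state.adapters:
        raise KeyError(f"unknown barcode {predicted_barcode!r}")
    tallies = state._tallies()
    seen = [v for v in tallies.values() if v > 0]
    threshold = state.slack * (sum(seen) / len(seen)) if seen else float("inf")
    over = tallies[predicted_barcode] > threshold
    warmed_up = state.adapters[predicted_barcode] >= state.min_count
    decision = REJECT if over and warmed_up else ACCEPT
    state.adapters[predicted_barcode] += 1
    state.decisions.append((predicted_barcode, str(status), decision))
    return decision


def run_balancing_experiment(
    dataset: list[RawRead],
    model: DtwKernelSvmClassifier,
    balance: bool = True,
    balance_metric: str = "adapter_count",
    slack: float = 1.2,
    min_count: int = 10,
    conf_cutoff: float = 0.0,
    n_channels: int = 8,
    time_budget_samples: int = 400_000,
    rejection_penalty_samples: int = 1506,  # ~0.5 s of channel time at 3012 Hz
    adapter_only_fraction: float = 0.0,
    chunk_ms: float = 100.0,
    seg_cfg: SegmentationConfig | None = None,
    seed: int = 0,
    classifications: dict[str, LiveResult] | None = None,
) -> dict:
    """Fixed-time sequencing simulation with and without barcode balancing.

    Each channel works through a shuffled queue of reads; accepting a read
    consumes its full length, rejecting frees the channel after the
    classification latency plus a penalty.  A configurable fraction of
    reads is adapter-only: they are classified like any adapter but yield
    no sequencer output, and the read/base tallies are corrected against
    that output.  Reports per-barcode accepted counts (by true label),
    Gini, and the decision log.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    ids = [r.read_id for r in dataset]
    if len(set(ids)) != len(ids):
        raise ValueError("dataset read_ids must be unique")
    seg_cfg = seg_cfg or SegmentationConfig()
    rng = np.random.default_rng(seed)
    barcodes = [str(c) for c in model.classes_ if c != NOISE_LABEL]
    state = BalancerState(barcodes, balance_metric=balance_metric, slack=slack, min_count=min_count)
    cache = classifications if classifications is not None else {}

    adapter_only = rng.random(len(dataset)) < adapter_only_fraction
    order = rng.permutation(len(dataset))
    queues: list[list[int]] = [[] for _ in range(n_channels)]
    for pos, idx in enumerate(order):
        queues[pos % n_channels].append(int(idx))

    accepted_counts: dict[str, int] = {}
    log: list[dict] = []
    chunk_len = int(round(chunk_ms * dataset[0].sample_rate / 1000.0))
    for ch in range(n_channels):
        clock = 0
        for idx in queues[ch]:
            if clock >= time_budget_samples:
                break
            read = dataset[idx]
            res = cache.get(read.read_id)
            if res is None:
                res = live_classify(
                    _single_read_chunks(read, chunk_len), model, seg_cfg, conf_cutoff=conf_cutoff
                )
                cache[read.read_id] = res
            if balance:
                decision = decide(state, res.label, res.confidence, conf_cutoff, res.status)
            else:
                decision = ACCEPT
                if res.status == STATUS_CLASSIFIED:
                    state.adapters[res.label] = state.adapters.get(res.label, 0) + 1
            truth_label = read.truth.barcode_label if read.truth else "?"
            if decision == REJECT:
                # a rejection always frees the channel before the read would end
                consumed = min(res.samples_consumed + rejection_penalty_samples,
                               max(read.signal.size - 1, 1))
                consumed = min(consumed, time_budget_samples - clock)
            else:
                # the run may end mid-read; a truncated final read is not counted
                consumed = min(read.signal.size, time_budget_samples - clock)
                completed = consumed == read.signal.size
                if completed and not adapter_only[idx]:  # sequencer output confirms a real read
                    accepted_counts[truth_label] = accepted_counts.get(truth_label, 0) + 1
                    if res.status == STATUS_CLASSIFIED:
                        state.reads[res.label] = state.reads.get(res.label, 0) + 1
                        state.bases[res.label] = state.bases.get(res.label, 0) + read.signal.size
            log.append(
                {
                    "read_id": read.read_id,
                    "true_label": truth_label,
                    "predicted": res.label,
                    "confidence": res.confidence,
                    "status": res.status,
                    "decision": decision,
                    "samples_consumed": consumed,
                    "adapter_only": bool(adapter_only[idx]),
                }
            )
            clock += consumed

    counts = {b: accepted_counts.get(b, 0) for b in barcodes}
    positive = [c for c in counts.values() if c >= 0]
    report = {
        "balance": balance,
        "per_barcode_counts": counts,
        "total_accepted": int(sum(counts.values())),
        "gini": gini(positive) if sum(positive) > 0 else float("nan"),
        "decision_log": log,
        "state": state,
    }
    return report


def _single_read_chunks(read: RawRead, chunk_len: int):
    for off in range(0, read.signal.size, chunk_len):
        yield StreamChunk(0, read.read_id, 0, read.signal[off : off + chunk_len], off == 0)
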