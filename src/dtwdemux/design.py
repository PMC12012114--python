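"""De novo barcode design by DTW-distance maximization.

The search space of barcode *sets* is astronomically large (choosing 12
barcodes of length 18 means C(4^18, 12) ~ 2.3e121 sets), so design runs in
three stages: (1) build a family of wave-like target signal patterns with
high mutual DTW distance, (2) per target, hill-climb over sequences whose
predicted squiggle (from a k-mer model, restricted to direction-robust
k-mers) matches the target, keeping the top candidates, and (3) select the
final set from the pooled candidates by solving the Maximal Diversity
Problem — maximize the summed pairwise DTWD of the chosen k — with a
greedy + local-exchange heuristic (exhaustive enumeration is available for
small instances).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .dtw import DtwConfig, dtwd, pairwise_dtwd
from .kmers import KmerModel, bidirectional_kmers, predict_levels
from .signal import normalize

__all__ = [
    "design_space_size",
    "TargetPattern",
    "make_targets",
    "Candidate",
    "CandidatePool",
    "score_candidates",
    "SelectionMask",
    "solve_mdp",
    "DesignResult",
    "design_barcodes",
]

_BASES = "ACGT"


def design_space_size(L: int = 18, k: int = 12) -> float:
    """Number of distinct k-sets of length-L barcodes, C(4^L, k), via log-gamma."""
    n = 4.0**L
    log_c = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    return math.exp(log_c)


# ---------------------------------------------------------------------------
# target patterns

@dataclasses.dataclass(frozen=True)
class TargetPattern:
    pattern_id: str
    values: np.ndarray


def _wave_family(length: int) -> list[TargetPattern]:
    t = np.arange(length) / length
    family = []
    for freq in (1, 2, 3, 4):
        for phase_i, phase in enumerate((0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi)):
            base = np.sin(2 * np.pi * freq * t + phase)
            for shape, wave in (("sine", base), ("square", np.sign(base))):
                values = normalize(wave)
                family.append(TargetPattern(f"f{freq}_p{phase_i}_{shape}", values))
    return family


def make_targets(n_targets: int = 12, length: int = 25, seed: int = 0) -> list[TargetPattern]:
    """Wave-like target patterns, greedily chosen to maximize the minimum
    pairwise DTWD within a sine/square frequency-phase grid."""
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    family = _wave_family(length)
    if n_targets > len(family):
        raise ValueError(f"waveform grid has only {len(family)} patterns")
    D = pairwise_dtwd([p.values for p in family])
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [int(i), int(j)]
    while len(selected) < n_targets:
        remaining = [x for x in range(len(family)) if x not in selected]
        min_d = D[np.ix_(remaining, selected)].min(axis=1)
        selected.append(remaining[int(np.argmax(min_d))])
    return [family[x] for x in selected]


# ---------------------------------------------------------------------------
# candidate search

@dataclasses.dataclass(frozen=True)
class Candidate:
    seq: str
    source_target: str
    score: float  # DTWD between the normalized predicted signal and the target


@dataclasses.dataclass
class CandidatePool:
    candidates: list[Candidate]

    @property
    def M(self) -> int:
        return len(self.candidates)

    def sequences(self) -> list[str]:
        return [c.seq for c in self.candidates]


class _KmerWalk:
    """Uniform random walks / mutations on the de Bruijn graph of allowed k-mers."""

    def __init__(self, allowed: set[str], k: int):
        if not allowed:
            raise ValueError("allowed k-mer set is empty")
        self.k = k
        # iteratively prune (k-1)-mer nodes with no outgoing edge so every
        # retained k-mer can be extended indefinitely
        alive = set(allowed)
        while True:
            nodes = {km[:-1] for km in alive}
            pruned = {km for km in alive if km[1:] in nodes}
            if pruned == alive:
                break
            alive = pruned
        if not alive:
            raise ValueError("no extensible sequence over the allowed k-mers")
        self.alive = sorted(alive)
        self.allowed = allowed
        self.next_bases: dict[str, str] = {}
        for km in alive:
            self.next_bases.setdefault(km[:-1], "")
        for km in alive:
            node = km[:-1]
            self.next_bases[node] = self.next_bases.get(node, "") + km[-1]

    def random_seq(self, L: int, rng: np.random.Generator) -> str:
        seq = self.alive[int(rng.integers(len(self.alive)))]
        while len(seq) < L:
            options = self.next_bases[seq[-(self.k - 1) :]]
            seq += options[int(rng.integers(len(options)))]
        return seq

    def valid(self, seq: str) -> bool:
        return all(seq[i : i + self.k] in self.allowed for i in range(len(seq) - self.k + 1))

    def mutate(self, seq: str, rng: np.random.Generator) -> str | None:
        pos = int(rng.integers(len(seq)))
        base = _BASES[int(rng.integers(4))]
        if base == seq[pos]:
            return None
        new = seq[:pos] + base + seq[pos + 1 :]
        lo = max(0, pos - self.k + 1)
        hi = min(len(seq) - self.k, pos)
        for i in range(lo, hi + 1):
            if new[i : i + self.k] not in self.allowed:
                return None
        return new


def score_candidates(
    targets: list[TargetPattern],
    model: KmerModel,
    allowed_kmers: set[str] | None = None,
    L: int = 18,
    top_n: int = 50,
    search_budget: int = 4000,
    seed: int = 0,
    restart_every: int = 200,
    dtw_cfg: DtwConfig | None = None,
) -> CandidatePool:
    """Stochastic hill-climbing search for barcodes matching each target.

    Every evaluated sequence is scored as the DTWD between its normalized
    predicted level sequence and the target; the ``top_n`` best distinct
    sequences per target enter the pool (duplicates across targets are kept,
    so the pool size is exactly ``len(targets) * top_n``).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if allowed_kmers is None:
        allowed_kmers = bidirectional_kmers(model)
    walk = _KmerWalk(allowed_kmers, model.k)
    dtw_cfg = dtw_cfg or DtwConfig()
    rng = np.random.default_rng(seed)

    pool: list[Candidate] = []
    for target in targets:
        def score(seq: str) -> float:
            return dtwd(normalize(predict_levels(seq, model)), target.values, dtw_cfg)

        seen: dict[str, float] = {}
        current = walk.random_seq(L, rng)
        seen[current] = cur_score = score(current)
        for step in range(search_budget):
            if step and step % restart_every == 0:
                current = walk.random_seq(L, rng)
                cur_score = seen.get(current) or score(current)
                seen[current] = cur_score
                continue
            proposal = walk.mutate(current, rng)
            if proposal is None:
                continue
            s = seen.get(proposal)
            if s is None:
                s = score(proposal)
                seen[proposal] = s
            if s < cur_score:
                current, cur_score = proposal, s
        while len(seen) < top_n:  # tiny budgets: pad with random valid sequences
            seq = walk.random_seq(L, rng)
            if seq not in seen:
                seen[seq] = score(seq)
        best = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))[:top_n]
        pool.extend(Candidate(seq, target.pattern_id, s) for seq, s in best)
    return CandidatePool(pool)


# ---------------------------------------------------------------------------
# Maximal Diversity Problem

@dataclasses.dataclass(frozen=True)
class SelectionMask:
    delta: np.ndarray  # 0/1 indicator over the pool
    objective: float  # sum over selected pairs i<j of D[i, j]

    @property
    def k(self) -> int:
        return int(self.delta.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.delta)


def _objective(D: np.ndarray, idx) -> float:
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0)


def solve_mdp(D: np.ndarray, k: int, method: str = "exchange",
              min_separation: float | None = None) -> SelectionMask:
    """Choose k of M items maximizing the summed pairwise distance.

    greedy: seed with the globally farthest pair, then repeatedly add the
    item with the largest summed distance to the current selection.
    exchange: greedy followed by best-improvement 1-swap local search.
    exhaustive: exact enumeration, gated to C(M, k) <= 1e6 instances.

    ``min_separation`` optionally forbids selected pairs closer than a
    floor: sum-diversity alone favours extreme points and will happily take
    near-duplicates of the same extreme, which is exactly wrong for a
    barcode set.  The greedy stage relaxes an infeasible floor by 10%
    steps, so a selection of size k always exists.
    """
    D = np.asarray(D, dtype=np.float64)
    M = D.shape[0]
    if D.shape != (M, M):
        raise ValueError("D must be square")
    if not (1 <= k <= M):
        raise ValueError(f"k={k} out of range for M={M}")
    floor = 0.0 if min_separation is None else float(min_separation)

    if method == "exhaustive":
        if math.comb(M, k) > 10**6:
            raise ValueError("instance too large for exhaustive enumeration")
        best_idx, best_obj = None, -np.inf
        for combo in itertools.combinations(range(M), k):
            if floor > 0 and k > 1:
                sub = D[np.ix_(combo, combo)]
                if sub[np.triu_indices(k, 1)].min() < floor:
                    continue
            obj = _objective(D, list(combo))
            if obj > best_obj:
                best_idx, best_obj = combo, obj
        if best_idx is None:
            raise ValueError("no feasible selection under min_separation")
        idx = list(best_idx)
    elif method in ("greedy", "exchange"):
        if k == 1:
            idx = [0]
        else:
            i, j = np.unravel_index(np.argmax(D), D.shape)
            idx = sorted({int(i), int(j)}) if i != j else [0, 1 % M]
            while len(idx) < k:
                rest = np.setdiff1d(np.arange(M), idx)
                if floor > 0:
                    feasible = rest[(D[np.ix_(rest, idx)] >= floor).all(axis=1)]
                    while feasible.size == 0:
                        floor *= 0.9
                        feasible = rest[(D[np.ix_(rest, idx)] >= floor).all(axis=1)]
                    rest = feasible
                sums = D[np.ix_(rest, idx)].sum(axis=1)
                idx.append(int(rest[np.argmax(sums)]))
        if method == "exchange":
            idx = _one_swap(D, idx, floor)
    else:
        raise ValueError(f"unknown method {method!r}")

    delta = np.zeros(M, dtype=np.int8)
    delta[list(idx)] = 1
    return SelectionMask(delta, _objective(D, sorted(idx)))


def _one_swap(D: np.ndarray, idx: list[int], floor: float = 0.0) -> list[int]:
    M = D.shape[0]
    sel = sorted(idx)
    while True:
        obj = _objective(D, sel)
        best_delta, best_move = 0.0, None
        outside = np.setdiff1d(np.arange(M), sel)
        for s in sel:
            others = [x for x in sel if x != s]
            base = D[s, others].sum()
            gains = D[np.ix_(outside, others)].sum(axis=1) - base
            if floor > 0:
                gains[~(D[np.ix_(outside, others)] >= floor).all(axis=1)] = -np.inf
            m = int(np.argmax(gains))
            if gains[m] > best_delta + 1e-12:
                best_delta, best_move = float(gains[m]), (s, int(outside[m]))
        if best_move is None:
            return sel
        s, c = best_move
        sel = sorted([x for x in sel if x != s] + [c])
        assert _objective(D, sel) > obj


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclasses.dataclass
class DesignResult:
    barcodes: dict[str, str]  # label -> sequence, e.g. BC01 -> ACGT...
    targets: list[TargetPattern]
    pool: CandidatePool
    selection: SelectionMask
    distance_matrix: np.ndarray  # pairwise DTWD of the selected predicted signals

    @property
    def min_pairwise_dtwd(self) -> float:
        D = self.distance_matrix
        off = D[~np.eye(D.shape[0], dtype=bool)]
        return float(off.min())


def design_barcodes(
    model: KmerModel,
    n_targets: int = 12,
    top_n: int = 50,
    k: int = 12,
    L: int = 18,
    target_length: int = 25,
    tol: float | None = None,
    search_budget: int = 20000,
    seed: int = 0,
    method: str = "exchange",
    min_separation: float | str | None = "auto",
    dtw_cfg: DtwConfig | None = None,
) -> DesignResult:
    """Targets -> candidates -> pairwise DTWD -> MDP selection.

    The pool keeps duplicates across targets (its size is exactly
    ``n_targets * top_n``); the final selection is deduplicated, extending
    greedily if the MDP picked the same sequence twice.  By default the
    selection enforces a minimum pairwise separation (the lower quartile of
    the pool's distance distribution) so near-duplicate local optima of the
    candidate search cannot enter the set together.
    """
    dtw_cfg = dtw_cfg or DtwConfig()
    targets = make_targets(n_targets, target_length, seed)
    allowed = bidirectional_kmers(model, tol)
    pool = score_candidates(targets, model, allowed, L, top_n, search_budget, seed, dtw_cfg=dtw_cfg)

    signals = [normalize(predict_levels(c.seq, model)) for c in pool.candidates]
    D = pairwise_dtwd(signals, cfg=dtw_cfg)
    if min_separation == "auto":
        min_separation = float(np.quantile(D[np.triu_indices(pool.M, 1)], 0.25))
    mask = solve_mdp(D, k, method, min_separation=min_separation)

    ordered = sorted(mask.indices, key=lambda i: -D[i, mask.indices].sum())
    seqs: list[str] = []
    for i in ordered:
        if pool.candidates[i].seq not in seqs:
            seqs.append(pool.candidates[i].seq)
    if len(seqs) < k:  # MDP selected duplicate sequences: extend greedily
        chosen = set(seqs)
        rest = sorted(
            (i for i in range(pool.M) if pool.candidates[i].seq not in chosen),
            key=lambda i: -D[i, mask.indices].sum(),
        )
        for i in rest:
            if pool.candidates[i].seq not in chosen:
                seqs.append(pool.candidates[i].seq)
                chosen.add(pool.candidates[i].seq)
            if len(seqs) == k:
                break
    barcodes = {f"BC{n + 1:02d}": s for n, s in enumerate(seqs[:k])}
    sel_signals = [normalize(predict_levels(s, model)) for s in barcodes.values()]
    return DesignResult(barcodes, targets, pool, mask, pairwise_dtwd(sel_signals, cfg=dtw_cfg))
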