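"""Adaptive-sampling balancer: streaming, live classification, decisions,
Gini accounting."""

import numpy as np
import pytest

import dtwdemux as dx
from dtwdemux.balance import ACCEPT, NO_DECISION, REJECT, _single_read_chunks, decide, gini
from dtwdemux.classify import STATUS_CLASSIFIED, STATUS_NOISE


# ---------------------------------------------------------------------------
# gini

def test_gini_uniform_is_zero():
    assert gini([10, 10, 10, 10]) == 0.0


def test_gini_hand_computed():
    assert gini([0, 0, 0, 100]) == pytest.approx(0.75)


def test_gini_scale_invariance():
    rng = np.random.default_rng(0)
    x = rng.integers(1, 100, size=12)
    for c in (0.5, 3.0, 1000.0):
        assert gini(c * x) == pytest.approx(gini(x), abs=1e-12)


def test_gini_validation():
    with pytest.raises(ValueError):
        gini([0, 0, 0])
    with pytest.raises(ValueError):
        gini([-1, 2])


# ---------------------------------------------------------------------------
# streaming

def test_chunk_sizes_and_reconstruction(kmer_model, barcodes4):
    read = dx.simulate_read(list(barcodes4.values())[0], kmer_model, dx.SimConfig(seed=1))
    chunks = list(dx.stream_reads([read], chunk_ms=100.0))
    assert all(len(c.samples) == 301 for c in chunks[:-1])  # round(0.1 * 3012)
    assert chunks[0].is_read_start and not chunks[1].is_read_start
    rebuilt = np.concatenate([c.samples for c in chunks])
    np.testing.assert_array_equal(rebuilt, read.signal)


def test_round_robin_preserves_per_read_order(kmer_model, barcodes4):
    cfg = dx.SimConfig(seed=2, rna_body_len_nt=20, polyA_len_nt=20)
    reads = dx.simulate_dataset(barcodes4, 2, 0.0, cfg, kmer_model)
    chunks = list(dx.stream_reads(reads, n_channels=2, seed=0))
    by_read: dict[str, list[int]] = {}
    for c in chunks:
        by_read.setdefault(c.read_id, []).append(len(c.samples))
    for read in reads:
        assert sum(by_read[read.read_id]) == read.signal.size
    # within a channel, a read's chunks are contiguous and ordered
    for ch in (0, 1):
        seen = []
        for c in chunks:
            if c.channel == ch and c.is_read_start:
                seen.append(c.read_id)
        assert len(seen) == len(set(seen))


# ---------------------------------------------------------------------------
# live classification

def test_live_classification_latency_and_agreement(clf4, kmer_model, barcodes4):
    """The live decision lands within two chunks of the poly(A) onset and
    agrees with the offline prediction for nearly all clean reads."""
    cfg = dx.SimConfig(seed=9)
    rng = np.random.default_rng(5)
    chunk_len = 301
    agree = total = 0
    for label, seq in list(barcodes4.items()) * 10:
        read = dx.simulate_read(seq, kmer_model, cfg, rng=rng, label=label)
        res = dx.live_classify(_single_read_chunks(read, chunk_len), clf4)
        onset = read.truth.adapter_end_idx
        assert res.status != NO_DECISION
        assert onset - chunk_len <= res.samples_consumed <= onset + 4 * chunk_len
        fp = dx.extract_fingerprint(read)
        offline = clf4.classify(fp.values).iloc[0]["predicted_label"]
        total += 1
        agree += res.label == offline
    assert agree / total >= 0.98


def test_live_classification_no_polya_times_out(clf4, kmer_model, barcodes4):
    reads = dx.simulate_dataset(barcodes4, 1, 0.5, dx.SimConfig(seed=10), kmer_model,
                                corruption_ops=("no_polya",))
    noise = [r for r in reads if r.truth.barcode_label == dx.NOISE_LABEL][0]
    res = dx.live_classify(_single_read_chunks(noise, 301), clf4, max_samples=20000)
    assert res.status == NO_DECISION


# ---------------------------------------------------------------------------
# decisions

def _state(**kw):
    return dx.BalancerState(["BC01", "BC02", "BC03", "BC04"], **kw)


def test_decide_equal_tallies_accept():
    st = _state()
    st.adapters.update({"BC01": 5, "BC02": 5, "BC03": 5, "BC04": 5})
    for b in st.barcodes:
        assert decide(st, b, 0.9) == ACCEPT


def test_decide_overrepresented_rejected():
    st = _state(slack=1.2)
    st.adapters.update({"BC01": 100, "BC02": 10, "BC03": 10, "BC04": 10})
    assert decide(st, "BC01", 0.9) == REJECT  # 100 > 1.2 * 32.5
    assert decide(st, "BC02", 0.9) == ACCEPT


def test_decide_unknown_identity_accepted():
    st = _state()
    st.adapters.update({"BC01": 10**6})
    assert decide(st, "BC01", 0.9, status=STATUS_NOISE) == ACCEPT
    assert decide(st, None, float("nan"), status="qc_fail") == ACCEPT
    assert decide(st, "BC01", 0.1, conf_cutoff=0.5) == ACCEPT


def test_decide_unknown_barcode_errors():
    with pytest.raises(KeyError):
        decide(_state(), "BC99", 0.9)


def test_decide_updates_tallies_after_decision():
    st = _state()
    decide(st, "BC01", 0.9)
    assert st.adapters["BC01"] == 1
    assert st.decisions[-1] == ("BC01", STATUS_CLASSIFIED, ACCEPT)


# ---------------------------------------------------------------------------
# balancing experiment

@pytest.fixture(scope="module")
def skewed_setup(kmer_model):
    res = dx.design_barcodes(kmer_model, k=2, n_targets=4, top_n=20, search_budget=2000, seed=5)
    bcs = res.barcodes
    train = dx.simulate_fingerprints(bcs, 60, sim_cfg=dx.SimConfig(seed=11), kmer_model=kmer_model)
    clf = dx.DtwKernelSvmClassifier(random_state=0).fit(train.fingerprints, train.labels)
    return bcs, clf


def _skewed_reads(bcs, kmer_model, seed, n_major=120, n_minor=12):
    labels = list(bcs)
    cfg = dx.SimConfig(seed=seed, rna_body_len_nt=120)
    return dx.simulate_dataset(bcs, {labels[0]: n_major, labels[1]: n_minor}, 0.0, cfg, kmer_model)


def test_balancing_reduces_gini_and_protects_minority(skewed_setup, kmer_model):
    bcs, clf = skewed_setup
    cache = {}
    reads = _skewed_reads(bcs, kmer_model, seed=900)
    kw = dict(n_channels=4, time_budget_samples=250_000, seed=1, classifications=cache)
    bal = dx.run_balancing_experiment(reads, clf, balance=True, **kw)
    ctl = dx.run_balancing_experiment(reads, clf, balance=False, **kw)
    assert bal["gini"] < ctl["gini"]
    assert min(bal["per_barcode_counts"].values()) >= min(ctl["per_barcode_counts"].values())


def test_rejections_consume_less_than_full_reads(skewed_setup, kmer_model):
    bcs, clf = skewed_setup
    reads = _skewed_reads(bcs, kmer_model, seed=901)
    lengths = {r.read_id: r.signal.size for r in reads}
    rep = dx.run_balancing_experiment(reads, clf, balance=True, n_channels=4,
                                      time_budget_samples=250_000, seed=2)
    rejections = [d for d in rep["decision_log"] if d["decision"] == REJECT]
    assert rejections
    assert all(d["samples_consumed"] < lengths[d["read_id"]] for d in rejections)


def test_time_budget_accounting(skewed_setup, kmer_model):
    """Total consumed channel time never exceeds budget x channels."""
    bcs, clf = skewed_setup
    reads = _skewed_reads(bcs, kmer_model, seed=902)
    budget, channels = 150_000, 3
    rep = dx.run_balancing_experiment(reads, clf, balance=True, n_channels=channels,
                                      time_budget_samples=budget, seed=3)
    consumed = sum(d["samples_consumed"] for d in rep["decision_log"])
    assert consumed <= budget * channels


def test_unbalanced_output_tracks_input_skew(skewed_setup, kmer_model):
    bcs, clf = skewed_setup
    reads = _skewed_reads(bcs, kmer_model, seed=903, n_major=100, n_minor=10)
    rep = dx.run_balancing_experiment(reads, clf, balance=False, n_channels=4,
                                      time_budget_samples=10**9, seed=4)
    counts = rep["per_barcode_counts"]
    frac = counts[list(bcs)[1]] / sum(counts.values())
    assert frac == pytest.approx(10 / 110, abs=0.05)


def test_experiment_deterministic(skewed_setup, kmer_model):
    bcs, clf = skewed_setup
    reads = _skewed_reads(bcs, kmer_model, seed=904)
    kw = dict(n_channels=4, time_budget_samples=200_000, seed=5)
    a = dx.run_balancing_experiment(reads, clf, balance=True, **kw)
    b = dx.run_balancing_experiment(reads, clf, balance=True, **kw)
    assert a["per_barcode_counts"] == b["per_barcode_counts"]
    assert [d["decision"] for d in a["decision_log"]] == [d["decision"] for d in b["decision_log"]]


def test_adapter_only_reads_corrected(skewed_setup, kmer_model):
    """Adapter-only molecules are classified like any adapter but never
    contribute to the accepted read counts."""
    bcs, clf = skewed_setup
    reads = _skewed_reads(bcs, kmer_model, seed=905, n_major=40, n_minor=40)
    rep = dx.run_balancing_experiment(reads, clf, balance=False, n_channels=2,
                                      time_budget_samples=10**9,
                                      adapter_only_fraction=0.5, seed=6)
    n_adapter_only = sum(d["adapter_only"] for d in rep["decision_log"])
    assert n_adapter_only > 0
    assert rep["total_accepted"] == len(reads) - n_adapter_only
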