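"""DTW-kernel SVM classification, confidence, calibration, evaluation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import dtwdemux as dx
from dtwdemux.classify import (
    STATUS_CLASSIFIED,
    STATUS_NOISE,
    STATUS_QC_FAIL,
    STATUS_UNCLASSIFIED,
    calibration_thresholds,
    evaluate,
    load_model,
    save_model,
)


def test_training_self_consistency(clf4, train4):
    """Well-separated simulated barcodes: near-perfect accuracy on the
    training inputs themselves."""
    acc = (clf4.predict(train4.fingerprints) == train4.labels).mean()
    assert acc >= 0.99


def test_estimator_api(clf4):
    params = clf4.get_params()
    assert params["gamma"] == 1.2 and params["C"] == 1.0
    fresh = clone(clf4)
    assert fresh.get_params() == params


def test_probability_and_confidence_invariants(clf4, test4):
    pred = clf4.classify(test4.fingerprints, conf_cutoff=0.3, read_ids=test4.read_ids)
    pcols = [c for c in pred.columns if c.startswith("p_")]
    probs = pred[pcols].to_numpy()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert (probs >= 0).all()
    top2 = np.sort(probs, axis=1)[:, -2:]
    np.testing.assert_allclose(pred["confidence"], top2[:, 1] - top2[:, 0], atol=1e-12)
    # predicted label is the argmax of the probability vector
    argmax_labels = [pcols[i][2:] for i in probs.argmax(axis=1)]
    assert (pred["predicted_label"] == argmax_labels).all()
    # status consistent with the cutoff
    below = pred["confidence"] < 0.3
    assert (pred.loc[below, "status"] == STATUS_UNCLASSIFIED).all()
    assert (pred.loc[~below, "status"] == STATUS_CLASSIFIED).all()


def test_qc_failed_rows_reported_not_dropped(clf4):
    X = np.vstack([np.full(25, np.nan), np.zeros(25)])
    pred = clf4.classify(X)
    assert pred.loc[0, "status"] == STATUS_QC_FAIL
    assert pred.loc[1, "status"] in (STATUS_CLASSIFIED, STATUS_UNCLASSIFIED)


def test_zero_cutoff_classifies_everything(clf4, test4):
    pred = clf4.classify(test4.fingerprints, conf_cutoff=0.0)
    assert (pred["status"] != STATUS_UNCLASSIFIED).all()


def test_noise_class_and_status(kmer_model, barcodes4, train4):
    """With a NOISE stratum in training, noise predictions get noise status
    regardless of the confidence cutoff."""
    noisy = dx.simulate_fingerprints(
        barcodes4, 40, noise_fraction=0.25, sim_cfg=dx.SimConfig(seed=55),
        kmer_model=kmer_model, corruption_ops=("plateau", "truncate"),
    )
    clf = dx.DtwKernelSvmClassifier(random_state=0).fit(noisy.fingerprints, noisy.labels)
    assert dx.NOISE_LABEL in clf.classes_
    pred = clf.classify(noisy.fingerprints, conf_cutoff=1.1)  # everything below cutoff
    noise_rows = pred["predicted_label"] == dx.NOISE_LABEL
    assert noise_rows.any()
    assert (pred.loc[noise_rows, "status"] == STATUS_NOISE).all()
    assert (pred.loc[~noise_rows, "status"] == STATUS_UNCLASSIFIED).all()


def test_model_roundtrip_bit_identical(tmp_path, clf4, test4):
    save_model(clf4, tmp_path / "model")
    loaded, table = load_model(tmp_path / "model")
    assert table is None
    p1 = clf4.predict_proba(test4.fingerprints[:100])
    p2 = loaded.predict_proba(test4.fingerprints[:100])
    np.testing.assert_array_equal(p1, p2)


def test_fingerprint_length_mismatch(clf4):
    with pytest.raises(ValueError, match="length"):
        clf4.predict_proba(np.zeros((3, 10)))


def test_fit_determinism(train4):
    a = dx.DtwKernelSvmClassifier(random_state=7).fit(train4.fingerprints, train4.labels)
    b = dx.DtwKernelSvmClassifier(random_state=7).fit(train4.fingerprints, train4.labels)
    X = train4.fingerprints[:50]
    np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


# ---------------------------------------------------------------------------
# calibration (accuracy-targeted confidence thresholds)

def _synthetic_predictions(rng, n, error_rate):
    """Predictions for one barcode with a controlled error rate: correct
    reads draw high confidences, misclassified reads lower ones."""
    wrong = rng.random(n) < error_rate
    conf = np.where(wrong, rng.beta(2, 4, n), rng.beta(6, 1.5, n))
    pred = np.full(n, "BC01")
    truth = np.where(wrong, "BC02", "BC01")
    return pred, conf, truth


def test_calibration_clamping_branches():
    rng = np.random.default_rng(0)
    # zero error: threshold 0 at every target
    pred, conf, truth = _synthetic_predictions(rng, 500, 0.0)
    table = calibration_thresholds(pred, conf, truth, [95, 99, 99.9], barcodes=["BC01"])
    assert table.error_rates["BC01"] == 0.0
    assert all(t == 0.0 for t in table.thresholds["BC01"].values())
    # E_b = 2%, A_t = 95: q = 1 - 5/2 < 0, clamped to 0
    wrong = np.zeros(500, dtype=bool)
    wrong[:10] = True
    conf = np.linspace(0.01, 0.99, 500)
    truth = np.where(wrong, "BC02", "BC01")
    table = calibration_thresholds(np.full(500, "BC01"), conf, truth, [95.0], barcodes=["BC01"])
    assert table.error_rates["BC01"] == pytest.approx(2.0)
    assert table.thresholds["BC01"][95.0] == 0.0


def test_calibration_quantile_matches_formula():
    """E_b = 10%, A_t = 99 -> q = 0.9: the threshold is the 0.9-quantile of
    the misclassified confidences."""
    rng = np.random.default_rng(1)
    pred, conf, truth = _synthetic_predictions(rng, 5000, 0.10)
    table = calibration_thresholds(pred, conf, truth, [99.0], barcodes=["BC01"])
    wrong_conf = conf[truth != "BC01"]
    e_b = table.error_rates["BC01"]
    q = 1 - (100 - 99.0) / e_b
    assert table.thresholds["BC01"][99.0] == pytest.approx(np.quantile(wrong_conf, q))


def test_calibration_achieves_target_on_fresh_draw():
    """Applying the calibrated threshold to an independent draw from the
    same generative process yields accuracy >= A_t - 0.5pp."""
    rng = np.random.default_rng(2)
    pred, conf, truth = _synthetic_predictions(rng, 20000, 0.10)
    table = calibration_thresholds(pred, conf, truth, [99.0], barcodes=["BC01"])
    T = table.thresholds["BC01"][99.0]
    pred2, conf2, truth2 = _synthetic_predictions(rng, 20000, 0.10)
    keep = conf2 > T
    observed = 100.0 * (truth2[keep] == "BC01").mean()
    assert observed >= 99.0 - 0.5


def test_calibration_threshold_monotone_in_target():
    rng = np.random.default_rng(3)
    pred, conf, truth = _synthetic_predictions(rng, 10000, 0.15)
    targets = [95.0, 97.0, 99.0, 99.5]
    table = calibration_thresholds(pred, conf, truth, targets, barcodes=["BC01"])
    ts = [table.thresholds["BC01"][a] for a in targets]
    assert all(a <= b + 1e-12 for a, b in zip(ts, ts[1:]))
    assert all(0.0 <= t <= 1.0 for t in ts)


def test_calibration_never_predicted_barcode_flagged():
    table = calibration_thresholds(["BC01"] * 5, [0.9] * 5, ["BC01"] * 5, [99.0],
                                   barcodes=["BC01", "BC02"])
    assert "BC02" in table.undefined_barcodes
    assert table.threshold("BC02", 99.0) is None


def test_calibrated_classify_uses_per_barcode_thresholds(clf4, kmer_model, barcodes4):
    calib = dx.simulate_fingerprints(barcodes4, 50, sim_cfg=dx.SimConfig(seed=60), kmer_model=kmer_model)
    table = dx.calibrate(clf4, calib, target_accuracies=(99.0,))
    fresh = dx.simulate_fingerprints(barcodes4, 30, sim_cfg=dx.SimConfig(seed=61), kmer_model=kmer_model)
    pred = clf4.classify(fresh.fingerprints, calibration=table, target_accuracy=99.0)
    assert set(pred["status"]) <= {STATUS_CLASSIFIED, STATUS_UNCLASSIFIED, STATUS_NOISE}


# ---------------------------------------------------------------------------
# evaluation

def test_evaluate_perfect_predictions():
    truth = np.array(["A", "B"] * 50)
    pred = pd.DataFrame({
        "read_id": [f"r{i}" for i in range(100)],
        "predicted_label": truth,
        "confidence": np.ones(100),
        "status": [STATUS_CLASSIFIED] * 100,
    })
    m = evaluate(pred, truth)
    assert m["accuracy"] == 1.0
    assert m["unclassified_pct"] == 0.0
    assert all(v["recall"] == 1.0 for v in m["per_class"].values())
    cm = np.asarray(m["confusion_matrix"])
    np.testing.assert_allclose(cm.sum(axis=1), 1.0, atol=1e-9)


def test_evaluate_noise_reads_omitted():
    truth = np.array(["A", "A", "B", "B"])
    pred = pd.DataFrame({
        "read_id": list("wxyz"),
        "predicted_label": ["A", "NOISE", "B", "A"],
        "confidence": [0.9, 0.8, 0.9, 0.1],
        "status": [STATUS_CLASSIFIED, STATUS_NOISE, STATUS_CLASSIFIED, STATUS_UNCLASSIFIED],
    })
    m = evaluate(pred, truth)
    assert m["accuracy"] == 1.0  # only the two classified reads count
    assert m["noise_pct"] == 25.0
    assert m["unclassified_pct"] == pytest.approx(100.0 / 3)


def test_accuracy_yield_tradeoff_monotone(clf4, kmer_model, barcodes4):
    """Raising the confidence cutoff never lowers accuracy and never raises
    the classified fraction."""
    for seed in range(5):
        test = dx.simulate_fingerprints(barcodes4, 30, sim_cfg=dx.SimConfig(seed=300 + seed, noise_sd=15.0),
                                        kmer_model=kmer_model)
        pred = clf4.classify(test.fingerprints, conf_cutoff=0.0)
        m = evaluate(pred, test.labels)
        accs = [c["accuracy"] for c in m["accuracy_yield_curve"]]
        fracs = [c["classified_fraction"] for c in m["accuracy_yield_curve"]]
        accs = [a for a in accs if not np.isnan(a)]
        tol = 1.0 / len(test)  # one-read discreteness
        assert all(a <= b + tol for a, b in zip(accs, accs[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(fracs, fracs[1:]))


def test_fewer_classes_never_hurts_accuracy(kmer_model):
    """Restricting the same data from 12 to 4 barcode classes never lowers
    accuracy at a fixed cutoff."""
    res = dx.design_barcodes(kmer_model, seed=1)
    bcs12 = res.barcodes
    bcs4 = dict(list(bcs12.items())[:4])
    for seed in range(5):
        noise = 22.0  # push accuracy off the ceiling so the contrast is visible
        tr12 = dx.simulate_fingerprints(bcs12, 40, sim_cfg=dx.SimConfig(seed=500 + seed, noise_sd=noise),
                                        kmer_model=kmer_model)
        te12 = dx.simulate_fingerprints(bcs12, 25, sim_cfg=dx.SimConfig(seed=600 + seed, noise_sd=noise),
                                        kmer_model=kmer_model)
        accs = {}
        for bcs, name in ((bcs12, 12), (bcs4, 4)):
            keep_tr = np.isin(tr12.labels, list(bcs))
            keep_te = np.isin(te12.labels, list(bcs))
            clf = dx.DtwKernelSvmClassifier(random_state=0).fit(
                tr12.fingerprints[keep_tr], tr12.labels[keep_tr])
            pred = clf.classify(te12.fingerprints[keep_te], conf_cutoff=0.0)
            mask = pred["status"] == STATUS_CLASSIFIED
            accs[name] = (pred.loc[mask, "predicted_label"].to_numpy()
                          == te12.labels[keep_te][mask]).mean()
        assert accs[4] >= accs[12] - 1e-9
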