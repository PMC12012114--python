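"""Barcode classification with a DTW-kernel SVM, confidence scoring,
accuracy-targeted calibration and evaluation.

The classifier is a one-vs-one SVM on the precomputed kernel
K(s1, s2) = exp(-gamma * DTWD(s1, s2)) with Platt-scaled class
probabilities (internal 5-fold CV, pairwise coupling — libsvm via
scikit-learn).  Each prediction carries a confidence score, the gap
between the top two class probabilities; predictions below a user cutoff
are "unclassified", and an explicit NOISE class absorbs signal artefacts
so they never count against accuracy.

Calibration maps a per-barcode target accuracy A_t (percent) to a
confidence threshold T: with baseline error rate E_b (percent) on a
held-out calibration set, T is the q-quantile of the misclassified reads'
confidences with q = 1 - (100 - A_t) / E_b, clamped to 0 when the baseline
already meets the target.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .dtw import DtwConfig, kernel_matrix
from .selection import LabeledFingerprintSet
from .simulate import NOISE_LABEL

__all__ = [
    "DtwKernelSvmClassifier",
    "CalibrationTable",
    "calibration_thresholds",
    "calibrate",
    "evaluate",
    "save_model",
    "load_model",
]

STATUS_CLASSIFIED = "classified"
STATUS_UNCLASSIFIED = "unclassified"
STATUS_NOISE = "noise"
STATUS_QC_FAIL = "qc_fail"

_FORMAT_VERSION = 1


class DtwKernelSvmClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-one SVM over the exponential DTW kernel.

    Parameters
    ----------
    gamma : kernel bandwidth of exp(-gamma * DTWD).
    C : SVM regularization.
    window : optional Sakoe-Chiba band half-width for the DTW alignment.
    random_state : seeds the internal Platt-scaling cross-validation.

    ``predict`` returns the argmax of the calibrated probabilities, so the
    predicted label is always consistent with the confidence score
    (p_top1 - p_top2) used downstream.
    """

    def __init__(self, gamma: float = 1.2, C: float = 1.0, window: int | None = None,
                 random_state: int | None = 0):
        self.gamma = gamma
        self.C = C
        self.window = window
        self.random_state = random_state

    def _dtw_cfg(self) -> DtwConfig:
        return DtwConfig(window=self.window, gamma=self.gamma)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, fingerprint_len) parallel to y")
        if np.isnan(X).any():
            raise ValueError("training fingerprints must not contain NaN")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 classes")
        K = kernel_matrix(X, cfg=self._dtw_cfg())
        svc = SVC(C=self.C, kernel="precomputed", probability=True, random_state=self.random_state)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)  # SVC(probability=True) deprecation
            try:
                svc.fit(K, y)
            except Exception:  # indefinite kernel: retry with diagonal jitter
                svc.fit(K + 1e-8 * np.eye(len(K)), y)
        self.svc_ = svc
        self.X_fit_ = X
        self.classes_ = svc.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _test_kernel(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"fingerprint length {X.shape[1]} != model's {self.n_features_in_}")
        return kernel_matrix(X, self.X_fit_, cfg=self._dtw_cfg())

    def predict_proba(self, X) -> np.ndarray:
        return self.svc_.predict_proba(self._test_kernel(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def classify(
        self,
        X,
        conf_cutoff: float = 0.0,
        read_ids=None,
        calibration: "CalibrationTable | None" = None,
        target_accuracy: float | None = None,
    ) -> pd.DataFrame:
        """Per-read prediction table with probabilities, confidence and status.

        NaN fingerprint rows are reported as ``qc_fail``.  A NOISE top class
        gives status ``noise`` regardless of the cutoff; otherwise the read
        is ``unclassified`` when its confidence falls below ``conf_cutoff``
        (or below the calibrated per-barcode threshold when a calibration
        table and target accuracy are supplied).
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        n = len(X)
        ids = np.asarray(read_ids) if read_ids is not None else np.array([f"read_{i:06d}" for i in range(n)])
        valid = ~np.isnan(X).any(axis=1)
        proba = np.full((n, len(self.classes_)), np.nan)
        if valid.any():
            proba[valid] = self.predict_proba(X[valid])

        labels = np.full(n, "", dtype=object)
        conf = np.full(n, np.nan)
        status = np.full(n, STATUS_QC_FAIL, dtype=object)
        if valid.any():
            p = proba[valid]
            top2 = np.sort(p, axis=1)[:, -2:]
            conf[valid] = top2[:, 1] - top2[:, 0]
            labels[valid] = self.classes_[np.argmax(p, axis=1)]
            use_cal = calibration is not None and target_accuracy is not None
            for i in np.flatnonzero(valid):
                if labels[i] == NOISE_LABEL:
                    status[i] = STATUS_NOISE
                    continue
                if use_cal:
                    t = calibration.threshold(str(labels[i]), target_accuracy)
                    # calibrated rule: retain strictly above the threshold
                    unclassified = t is None or conf[i] <= t
                else:
                    unclassified = conf[i] < conf_cutoff
                status[i] = STATUS_UNCLASSIFIED if unclassified else STATUS_CLASSIFIED

        out = pd.DataFrame({"read_id": ids, "predicted_label": labels, "confidence": conf, "status": status})
        for j, cls in enumerate(self.classes_):
            out[f"p_{cls}"] = proba[:, j]
        return out


@dataclasses.dataclass
class CalibrationTable:
    """Per-barcode baseline error rates and accuracy-to-threshold maps."""

    error_rates: dict[str, float]  # percent, NaN when the barcode was never predicted
    thresholds: dict[str, dict[float, float]]
    target_accuracies: tuple[float, ...]

    def threshold(self, barcode: str, target_accuracy: float) -> float | None:
        t = self.thresholds.get(barcode, {}).get(float(target_accuracy))
        return None if t is None or np.isnan(t) else t

    @property
    def undefined_barcodes(self) -> list[str]:
        return [b for b, e in self.error_rates.items() if np.isnan(e)]


def calibration_thresholds(
    pred_labels,
    confidences,
    true_labels,
    target_accuracies,
    barcodes=None,
) -> CalibrationTable:
    """Build a calibration table from held-out predictions.

    For each barcode b: E_b = 100 * (# misclassified among reads predicted
    as b) / (# predicted as b).  For each target accuracy A_t the threshold
    is 0 when E_b <= 100 - A_t, else the linear-interpolation q-quantile of
    the misclassified confidences with q = 1 - (100 - A_t) / E_b.
    """
    pred = np.asarray(pred_labels)
    conf = np.asarray(confidences, dtype=np.float64)
    truth = np.asarray(true_labels)
    targets = tuple(float(a) for a in target_accuracies)
    if barcodes is None:
        barcodes = [b for b in np.unique(truth) if b != NOISE_LABEL]
    error_rates: dict[str, float] = {}
    thresholds: dict[str, dict[float, float]] = {}
    for b in barcodes:
        mask = pred == b
        n_pred = int(mask.sum())
        if n_pred == 0:
            error_rates[str(b)] = float("nan")
            thresholds[str(b)] = {a: float("nan") for a in targets}
            continue
        wrong = mask & (truth != b)
        e_b = 100.0 * wrong.sum() / n_pred
        error_rates[str(b)] = e_b
        table: dict[float, float] = {}
        for a_t in targets:
            q = 1.0 - (100.0 - a_t) / e_b if e_b > 0 else -np.inf
            if q <= 0:
                table[a_t] = 0.0
            else:
                table[a_t] = float(np.quantile(conf[wrong], q, method="linear"))
        thresholds[str(b)] = table
    return CalibrationTable(error_rates, thresholds, targets)


def calibrate(
    model: DtwKernelSvmClassifier,
    calib_set: LabeledFingerprintSet,
    target_accuracies=(95.0, 96.0, 97.0, 98.0, 99.0, 99.5, 99.9),
) -> CalibrationTable:
    """Predict a held-out calibration set and derive per-barcode thresholds."""
    pred = model.classify(calib_set.fingerprints, conf_cutoff=0.0, read_ids=calib_set.read_ids)
    usable = pred["status"].isin([STATUS_CLASSIFIED, STATUS_UNCLASSIFIED]).to_numpy()
    barcodes = [c for c in model.classes_ if c != NOISE_LABEL]
    return calibration_thresholds(
        pred["predicted_label"].to_numpy()[usable],
        pred["confidence"].to_numpy()[usable],
        np.asarray(calib_set.labels)[usable],
        target_accuracies,
        barcodes=barcodes,
    )


def evaluate(predictions: pd.DataFrame, true_labels, cutoff_grid=None) -> dict:
    """Demultiplexing metrics against ground truth.

    Noise-status and QC-failed reads are omitted from accuracy, which is
    computed over classified reads only.  The unclassified fraction is
    taken over the noise-free, QC-passing reads.  The confusion matrix is
    recall-normalized (rows are true labels).  ``accuracy_yield_curve``
    re-thresholds the reported confidences over a cutoff grid.
    """
    truth = np.asarray(true_labels)
    status = predictions["status"].to_numpy()
    pred = predictions["predicted_label"].to_numpy()
    conf = predictions["confidence"].to_numpy(dtype=float)

    eligible = (status == STATUS_CLASSIFIED) | (status == STATUS_UNCLASSIFIED)
    classified = status == STATUS_CLASSIFIED
    out: dict = {
        "n_reads": int(len(truth)),
        "noise_pct": 100.0 * float((status == STATUS_NOISE).mean()),
        "qc_fail_pct": 100.0 * float((status == STATUS_QC_FAIL).mean()),
        "unclassified_pct": (
            100.0 * float((status[eligible] == STATUS_UNCLASSIFIED).mean()) if eligible.any() else float("nan")
        ),
    }
    if not classified.any():
        out.update(accuracy=float("nan"), flagged="no classified reads")
        return out

    y_true, y_pred = truth[classified], pred[classified]
    out["accuracy"] = float((y_true == y_pred).mean())
    labels = sorted(set(np.unique(y_true)) | set(np.unique(y_pred)))
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0.0
    )
    out["per_class"] = {
        str(lab): {"precision": float(p), "recall": float(r)} for lab, p, r in zip(labels, prec, rec)
    }
    out["macro_precision"] = float(prec.mean())
    out["macro_recall"] = float(rec.mean())
    cm = confusion_matrix(y_true, y_pred, labels=labels, normalize="true")
    out["confusion_labels"] = [str(x) for x in labels]
    out["confusion_matrix"] = cm.tolist()

    if cutoff_grid is None:
        cutoff_grid = np.round(np.arange(0.0, 1.0, 0.1), 10)
    curve = []
    base = eligible & (truth != NOISE_LABEL)
    for c in cutoff_grid:
        keep = base & (conf >= c)
        curve.append(
            {
                "cutoff": float(c),
                "classified_fraction": float(keep.sum() / max(base.sum(), 1)),
                "accuracy": float((pred[keep] == truth[keep]).mean()) if keep.any() else float("nan"),
            }
        )
    out["accuracy_yield_curve"] = curve
    return out


def save_model(model: DtwKernelSvmClassifier, path: str | Path,
               calibration: CalibrationTable | None = None) -> None:
    """Model archive: JSON metadata + binary arrays + fitted SVM state."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _FORMAT_VERSION,
        "gamma": model.gamma,
        "C": model.C,
        "window": model.window,
        "random_state": model.random_state,
        "classes": [str(c) for c in model.classes_],
        "fingerprint_len": int(model.n_features_in_),
    }
    if calibration is not None:
        meta["calibration"] = {
            "error_rates": calibration.error_rates,
            "thresholds": {b: {str(a): t for a, t in tab.items()} for b, tab in calibration.thresholds.items()},
            "target_accuracies": list(calibration.target_accuracies),
        }
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    np.save(path / "support_fingerprints.npy", model.X_fit_)
    joblib.dump(model.svc_, path / "svm.joblib")


def load_model(path: str | Path) -> tuple[DtwKernelSvmClassifier, CalibrationTable | None]:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta.get('format_version')}")
    model = DtwKernelSvmClassifier(
        gamma=meta["gamma"], C=meta["C"], window=meta["window"], random_state=meta["random_state"]
    )
    model.X_fit_ = np.load(path / "support_fingerprints.npy")
    model.svc_ = joblib.load(path / "svm.joblib")
    model.classes_ = model.svc_.classes_
    model.n_features_in_ = model.X_fit_.shape[1]
    calibration = None
    if "calibration" in meta:
        c = meta["calibration"]
        calibration = CalibrationTable(
            error_rates=c["error_rates"],
            thresholds={b: {float(a): t for a, t in tab.items()} for b, tab in c["thresholds"].items()},
            target_accuracies=tuple(c["target_accuracies"]),
        )
    return model, calibration
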