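"""Metrics and evaluation harnesses.

Classification reports follow the WEKA convention: per-class TP rate,
FP rate, precision, recall and ROC area computed one-vs-rest, plus their
support-weighted averages, and the (class-symmetric) Matthews correlation
coefficient.  Numeric targets are summarized by the Pearson correlation
coefficient and the relative absolute error.

Harnesses: leave-one-out cross-validation (all held-out predictions
pooled into a single confusion matrix), train-on-one / test-on-the-other
swapped evaluation, and the asymmetric critical-set overlap between two
models' predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import LinearSVC

from .features import FeatureTable
from .selection_ga import _resolve_class_weight

log = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def support(self) -> int:
        return self.tp + self.fn


def confusion_counts(y_true, y_pred, label) -> ConfusionCounts:
    t = np.asarray(y_true) == label
    p = np.asarray(y_pred) == label
    return ConfusionCounts(
        tp=int((t & p).sum()), fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()), fn=int((t & ~p).sum()),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    num = c.tp * c.tn - c.fp * c.fn
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    return num / den**0.5 if den > 0 else 0.0


def confusion_and_metrics(y_true, y_pred, scores=None, score_label=None) -> dict:
    """Per-class and support-weighted metrics for single-label classification.

    *scores* are optional real-valued decision scores oriented toward
    *score_label* (higher = more likely that class); ROC areas are omitted
    when absent.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    labels = sorted(set(y_true) | set(y_pred))
    if len(set(y_true)) < 2:
        log.warning("single-class ground truth; MCC defined as 0")

    per_class = {}
    for lab in labels:
        c = confusion_counts(y_true, y_pred, lab)
        tp_rate = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        fp_rate = c.fp / (c.fp + c.tn) if c.fp + c.tn else 0.0
        precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        entry = {
            "tp_rate": tp_rate, "fp_rate": fp_rate,
            "precision": precision, "recall": tp_rate,
            "support": c.support,
        }
        if scores is not None and len(set(y_true)) == 2:
            s = np.asarray(scores, dtype=float)
            oriented = s if lab == score_label else -s
            try:
                entry["roc_area"] = float(roc_auc_score(y_true == lab, oriented))
            except ValueError:
                pass
        per_class[lab] = entry

    total = sum(e["support"] for e in per_class.values())
    weighted = {}
    metric_names = ["tp_rate", "fp_rate", "precision", "recall"]
    if all("roc_area" in e for e in per_class.values()):
        metric_names.append("roc_area")
    for name in metric_names:
        weighted[name] = (
            sum(e[name] * e["support"] for e in per_class.values()) / total
            if total else 0.0
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y_true, y_pred)) if len(set(y_true)) > 1 else 0.0
    return {"per_class": per_class, "weighted": weighted, "mcc": mcc}


def regression_metrics(y_true, y_pred) -> dict:
    """Pearson correlation and relative absolute error (percent)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    cc = float(np.corrcoef(y_true, y_pred)[0, 1])
    denom = np.abs(y_true - y_true.mean()).sum()
    rae = 100.0 * np.abs(y_pred - y_true).sum() / denom if denom > 0 else float("nan")
    return {"correlation_coefficient": cc, "relative_absolute_error": rae}


# --- classifier contract ------------------------------------------------------

def make_classifier(spec: dict, classes=None):
    """Instantiate a classifier from a declarative spec.

    ``spec = {"name": "linear_svc" | "logistic", "params": {...},
    "class_weight": dict | preset | None}``.
    """
    name = spec.get("name", "linear_svc")
    params = dict(spec.get("params", {}))
    cw = spec.get("class_weight")
    if cw is not None and classes is not None:
        cw = _resolve_class_weight(cw, classes)
    if name == "linear_svc":
        return LinearSVC(class_weight=cw, dual=False, **params)
    if name == "logistic":
        return LogisticRegression(class_weight=cw, max_iter=1000, **params)
    raise ValueError(f"unknown classifier {name!r}")


def _decision_scores(clf, X):
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(X), dtype=float)
    return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)


def leave_one_out(table: FeatureTable, classifier_spec: dict) -> dict:
    """n single-instance held-out predictions pooled into one report."""
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy()
    if len(y) < 2:
        raise ValueError("need at least two instances")
    preds = np.empty(len(y), dtype=object)
    scores = np.empty(len(y), dtype=float)
    score_label = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train, test in LeaveOneOut().split(X):
            clf = make_classifier(classifier_spec, classes=np.unique(y[train]))
            clf.fit(X[train], y[train])
            preds[test[0]] = clf.predict(X[test])[0]
            scores[test[0]] = _decision_scores(clf, X[test])[0]
            score_label = clf.classes_[1]
    return confusion_and_metrics(y, preds, scores, score_label)


def swapped_test(train: FeatureTable, test: FeatureTable, classifier_spec: dict) -> dict:
    """Fit on one dataset, evaluate on the other (descriptors intersected)."""
    common = [c for c in train.descriptor_names if c in set(test.descriptor_names)]
    if not common:
        raise ValueError("train and test tables share no descriptors")
    if len(common) < len(train.descriptor_names) or len(common) < len(test.descriptor_names):
        log.warning(
            "descriptor mismatch: using the %d shared descriptors", len(common)
        )
    Xtr = train.X.loc[:, common].to_numpy(dtype=float)
    Xte = test.X.loc[:, common].to_numpy(dtype=float)
    ytr = train.y.to_numpy()
    yte = test.y.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = make_classifier(classifier_spec, classes=np.unique(ytr))
        clf.fit(Xtr, ytr)
        preds = clf.predict(Xte)
        scores = _decision_scores(clf, Xte)
    return confusion_and_metrics(yte, preds, scores, clf.classes_[1])


def model_overlap(pred_a, pred_b, critical_label="critical") -> float:
    """Percentage of a's critical calls also called critical by b.

    overlap(a->b) = 100 * |critical(a) & critical(b)| / |critical(a)|;
    asymmetric by design.  NaN when a calls nothing critical.
    """
    a = pd.Series(pred_a)
    b = pd.Series(pred_b)
    if not a.index.equals(b.index):
        raise ValueError("predictions must share instance ids")
    crit_a = set(a.index[a == critical_label])
    crit_b = set(b.index[b == critical_label])
    if not crit_a:
        return float("nan")
    return 100.0 * len(crit_a & crit_b) / len(crit_a)


def overlap_matrix(predictions: dict[str, pd.Series], critical_label="critical") -> pd.DataFrame:
    names = list(predictions)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = model_overlap(predictions[a], predictions[b], critical_label)
    return mat
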