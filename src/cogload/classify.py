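"""The four classifier families and the study's metric arithmetic.

Metrics follow the printed definitions, two of which are nonstandard:
F1 = 2·Sens·Spec/(Sens+Spec) (harmonic mean of sensitivity and
specificity, not of precision and recall) and AUC = (Sens+Spec)/2
(balanced accuracy).  ``conventional=True`` switches F1 to the standard
precision/recall form; a conventional ROC AUC cannot be derived from
confusion counts and is not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .types import ClassifierSpec, CogloadError, ConfusionCounts, ConfigurationError

__all__ = ["make_classifier", "train", "confusion", "metrics", "MetricSet"]


def make_classifier(spec: ClassifierSpec):
    """An unfitted scikit-learn estimator for a classifier spec.

    Defaults (overridable through ``spec.hyperparams``): SVMs with cost 1 —
    inhomogeneous degree-2 polynomial kernel or RBF with width 1/dimension;
    KNN with k=5, Euclidean distance weighting; a Gini decision tree of
    unlimited depth.
    """
    p = spec.params
    if spec.kind == "SVM_quadratic":
        return SVC(kernel="poly", degree=2, coef0=1.0, gamma="auto",
                   C=p.get("C", 1.0), random_state=spec.seed)
    if spec.kind == "SVM_rbf":
        return SVC(kernel="rbf", gamma=p.get("gamma", "auto"),
                   C=p.get("C", 1.0), random_state=spec.seed)
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=p.get("k", 5), weights="distance")
    return DecisionTreeClassifier(criterion=p.get("criterion", "gini"),
                                  max_depth=p.get("max_depth"),
                                  random_state=spec.seed)


def train(spec, X, y):
    """Fit a fresh classifier; both classes must be present."""
    if len(np.unique(y)) < 2:
        raise CogloadError("training requires both classes")
    est = make_classifier(spec) if isinstance(spec, ClassifierSpec) else clone(spec)
    return est.fit(np.asarray(X, dtype=float), np.asarray(y))


def confusion(predictions, truth, positive) -> ConfusionCounts:
    """2×2 counts with the stated positive class."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ConfigurationError("predictions and truth differ in length")
    pos_t = truth == positive
    pos_p = predictions == positive
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        positive_class=str(positive),
    )


@dataclass(frozen=True)
class MetricSet:
    """Sens/Spec/Prec/Acc/F1/AUC; undefined metrics are NaN and listed."""

    Sens: float
    Spec: float
    Prec: float
    Acc: float
    F1: float
    AUC: float
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("Sens", "Spec", "Prec", "Acc", "F1", "AUC")}


def metrics(cm: ConfusionCounts, conventional: bool = False) -> MetricSet:
    """Metric arithmetic from confusion counts.

    Zero denominators make the affected metric NaN and add its name to
    ``undefined`` — never a silent zero.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    sens = ratio(cm.TP, cm.TP + cm.FN, "Sens")
    spec = ratio(cm.TN, cm.TN + cm.FP, "Spec")
    prec = ratio(cm.TP, cm.TP + cm.FP, "Prec")
    acc = ratio(cm.TP + cm.TN, cm.total, "Acc")
    if conventional:
        f1 = ratio(2 * prec * sens, prec + sens, "F1") \
            if not (math.isnan(prec) or math.isnan(sens)) else math.nan
        if math.isnan(f1) and "F1" not in undefined:
            undefined.append("F1")
    else:
        if math.isnan(sens) or math.isnan(spec):
            undefined.append("F1")
            f1 = math.nan
        else:
            f1 = ratio(2 * sens * spec, sens + spec, "F1")
    if math.isnan(sens) or math.isnan(spec):
        undefined.append("AUC")
        auc = math.nan
    else:
        auc = 0.5 * (sens + spec)
    return MetricSet(sens, spec, prec, acc, f1, auc, tuple(undefined))
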