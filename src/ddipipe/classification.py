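"""Classifier validation on an independent dataset, with self-computed metrics.

A support vector machine (linear kernel, C = 1 by default) is trained on
the discovery dataset restricted to the marker genes and applied to a
held-out validation dataset integrated with the same per-array transform.
``case`` is the positive class. All metrics are computed here from first
principles:

    ACC = (TP + TN) / total        SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is defined as 0 (flagged and logged) when any factor of the
denominator vanishes. AUC is the Mann-Whitney statistic — the fraction of
(case, control) pairs in which the case's decision score exceeds the
control's, ties counted half — and the ROC curve is a threshold sweep over
the unique scores, whose trapezoidal area equals that statistic exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from sklearn.svm import SVC

from ddipipe._util import round_half_up
from ddipipe.integration import IntegratedDataset

logger = logging.getLogger(__name__)

POSITIVE = "case"
NEGATIVE = "control"


@dataclass
class ConfusionMatrix:
    """2x2 counts with ``case`` as the positive class."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass
class ClassificationReport:
    """Confusion counts, derived metrics, and the ROC curve of one validation run."""

    confusion: ConfusionMatrix
    ACC: float
    SEN: float
    SPE: float
    MCC: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    AUC: float = float("nan")
    undefined_metrics: list[str] = field(default_factory=list)

    def rounded(self) -> dict[str, float]:
        """2-decimal half-up values for comparison against printed tables."""
        return {
            "ACC": round_half_up(self.ACC),
            "SEN": round_half_up(self.SEN),
            "SPE": round_half_up(self.SPE),
            "MCC": round_half_up(self.MCC),
        }

    def to_dict(self) -> dict:
        cm = self.confusion
        return {
            "confusion": {"TP": cm.TP, "FN": cm.FN, "TN": cm.TN, "FP": cm.FP},
            "ACC": self.ACC,
            "SEN": self.SEN,
            "SPE": self.SPE,
            "MCC": self.MCC,
            "AUC": self.AUC,
            "rounded": self.rounded(),
            "roc_points": [list(p) for p in self.roc_points],
            "undefined_metrics": self.undefined_metrics,
        }


class Classifier(Protocol):
    """Anything with sklearn-style fit / predict / decision_function."""

    def fit(self, X, y): ...
    def predict(self, X): ...
    def decision_function(self, X): ...


def train_and_predict(
    train: IntegratedDataset,
    validation: IntegratedDataset,
    features: Sequence[str],
    classifier: Classifier | None = None,
    C: float = 1.0,
    kernel: str = "linear",
) -> tuple[list[str], np.ndarray]:
    """Fit on the discovery set, score the validation set; returns labels + scores.

    Features missing from either dataset are dropped with a logged warning;
    zero surviving features or a single-class training set raise. Decision
    scores are signed so that positive means ``case``.
    """
    feats = [g for g in features if g in train.values.index and g in validation.values.index]
    dropped = [g for g in features if g not in feats]
    if dropped:
        logger.warning(
            "dropping %d feature(s) missing from train/validation: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    if not feats:
        raise ValueError(f"no features survive intersection; missing: {list(features)[:10]}")
    y_train = train.groups.to_numpy()
    if len(set(y_train)) < 2:
        raise ValueError("training set contains a single class")
    X_train = train.values.loc[feats].to_numpy(dtype=float).T
    X_valid = validation.values.loc[feats].to_numpy(dtype=float).T
    model = classifier if classifier is not None else SVC(kernel=kernel, C=C)
    y_bin = (y_train == POSITIVE).astype(int)
    model.fit(X_train, y_bin)
    scores = np.asarray(model.decision_function(X_valid), dtype=float)
    labels = [POSITIVE if s > 0 else NEGATIVE for s in scores]
    return labels, scores


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """Count TP/FN/TN/FP with ``case`` positive."""
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted")
    valid = {POSITIVE, NEGATIVE}
    bad = (set(truth) | set(predicted)) - valid
    if bad:
        raise ValueError(f"labels must be in {valid}, got {sorted(bad)}")
    tp = fn = tn = fp = 0
    for t, p in zip(truth, predicted):
        if t == POSITIVE:
            tp += p == POSITIVE
            fn += p == NEGATIVE
        else:
            tn += p == NEGATIVE
            fp += p == POSITIVE
    return ConfusionMatrix(TP=tp, FN=fn, TN=tn, FP=fp)


def metrics(cm: ConfusionMatrix) -> ClassificationReport:
    """ACC/SEN/SPE/MCC from a confusion matrix; undefined ratios become 0, flagged."""
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            logger.warning("metric %s undefined (zero denominator), reported as 0", name)
            return 0.0
        return num / den

    acc = ratio(cm.TP + cm.TN, cm.total, "ACC")
    sen = ratio(cm.TP, cm.TP + cm.FN, "SEN")
    spe = ratio(cm.TN, cm.TN + cm.FP, "SPE")
    denom_sq = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if denom_sq == 0:
        undefined.append("MCC")
        logger.warning("metric MCC undefined (zero denominator), reported as 0")
        mcc = 0.0
    else:
        mcc = (cm.TP * cm.TN - cm.FP * cm.FN) / np.sqrt(denom_sq)
    return ClassificationReport(
        confusion=cm, ACC=acc, SEN=sen, SPE=spe, MCC=float(mcc), undefined_metrics=undefined
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[str]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (threshold sweep) and the Mann-Whitney AUC.

    AUC is the fraction of (case, control) pairs where the case outscores
    the control, ties half-weighted; the trapezoidal area under the swept
    ROC equals it exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    pos = scores[labels == POSITIVE]
    neg = scores[labels == NEGATIVE]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")

    # Mann-Whitney statistic by pair comparison (vectorized)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (wins + 0.5 * ties) / (pos.size * neg.size)

    # threshold sweep over unique scores, descending
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += sorted_labels[j] == POSITIVE
            fp += sorted_labels[j] == NEGATIVE
            j += 1
        points.append((fp / neg.size, tp / pos.size))
        i = j
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points, float(auc)


def validate(
    train: IntegratedDataset,
    validation: IntegratedDataset,
    features: Sequence[str],
    **kwargs,
) -> ClassificationReport:
    """End-to-end convenience: train, predict, and report all metrics."""
    labels, scores = train_and_predict(train, validation, features, **kwargs)
    truth = list(validation.groups.to_numpy())
    report = metrics(confusion(truth, labels))
    report.roc_points, report.AUC = roc_auc(scores, truth)
    return report
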