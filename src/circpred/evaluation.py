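"""Cross-validated, repeated balanced evaluation and performance metrics.

"Accuracy" throughout is balanced accuracy, (TPR + TNR) / 2, which is
insensitive to class imbalance and to the +/-1 label orientation.  Undefined
metrics (zero denominator, e.g. PPV with no positive predictions) are
reported as NaN, excluded from means, and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import classifier
from .datasets import SubDataset, make_balanced_replicates
from .kernels import KernelSpec

logger = logging.getLogger(__name__)

METRIC_NAMES = ("TPR", "TNR", "accuracy", "PPV", "auROC", "auPR")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positives are the +1 (circadian) class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(((y_true == 1) & (y_pred == 1)).sum()),
            TN=int(((y_true == -1) & (y_pred == -1)).sum()),
            FP=int(((y_true == -1) & (y_pred == 1)).sum()),
            FN=int(((y_true == 1) & (y_pred == -1)).sum()),
        )

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """TPR, TNR, balanced accuracy and PPV from confusion counts.

    Balanced accuracy averages the defined rates only, so an all-positive
    evaluation set (TNR undefined) yields accuracy = sensitivity.
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    tpr = ratio(cm.TP, cm.TP + cm.FN)
    tnr = ratio(cm.TN, cm.TN + cm.FP)
    ppv = ratio(cm.TP, cm.TP + cm.FP)
    rates = [r for r in (tpr, tnr) if not np.isnan(r)]
    acc = float(np.mean(rates)) if rates else float("nan")
    out = {"TPR": tpr, "TNR": tnr, "accuracy": acc, "PPV": ppv}
    undefined = [k for k, v in out.items() if np.isnan(v)]
    if undefined:
        logger.info("undefined metric(s) %s for %s", undefined, cm)
    return out


def kfold_split(
    labels: Sequence[int], k: int = 5, seed: int = 0
) -> list[np.ndarray]:
    """Stratified k-fold test index sets: disjoint, exhaustive, seeded."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs >= k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


@dataclass(frozen=True)
class Curves:
    """ROC and precision-recall curves with trapezoid-rule areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    precision: np.ndarray
    recall: np.ndarray
    aupr: float


def curves(labels: Sequence[int], scores: Sequence[float]) -> Curves:
    """Threshold-sweep ROC and PR curves from real-valued scores."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("curves need both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(labels, scores, pos_label=1)
    # precision_recall_curve returns recall in decreasing order
    aupr = float(np.trapezoid(precision[::-1], recall[::-1]))
    return Curves(
        fpr=fpr, tpr=tpr, auroc=auroc, precision=precision, recall=recall, aupr=aupr
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    C: float = 1.0,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[ConfusionMatrix], np.ndarray, np.ndarray]:
    """Stratified k-fold CV: per-fold confusions plus out-of-fold scores.

    Every instance is tested exactly once; fold models are fit (including
    their standardization statistics) on the training folds only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    test_sets = kfold_split(y, k=k, seed=seed)
    all_idx = np.arange(len(y))
    fold_cms = []
    oof_scores = np.zeros(len(y))
    oof_labels = np.zeros(len(y), dtype=int)
    for test_idx in test_sets:
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = classifier.fit(X[train_idx], y[train_idx], spec, C)
        labels, probs = model.predict(X[test_idx])
        oof_scores[test_idx] = model.decision_function(X[test_idx])
        oof_labels[test_idx] = labels
        fold_cms.append(ConfusionMatrix.from_predictions(y[test_idx], labels))
    return fold_cms, oof_scores, oof_labels


@dataclass
class EvaluationReport:
    """Per-replicate metrics with their mean and standard deviation."""

    per_replicate: pd.DataFrame  # rows = replicates, columns = METRIC_NAMES
    confusions: list[ConfusionMatrix]
    curve_list: list[Curves] = field(default_factory=list)

    @property
    def mean(self) -> pd.Series:
        return self.per_replicate.mean(skipna=True)

    @property
    def sd(self) -> pd.Series:
        return self.per_replicate.std(skipna=True, ddof=1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def repeated_balanced_eval(
    sub: SubDataset,
    spec: KernelSpec,
    C: float = 1.0,
    n_replicates: int = 10,
    k: int = 5,
    seed: int = 0,
    outer_repeats: int = 1,
) -> EvaluationReport:
    """The repeated balanced-undersampling CV protocol for one stratum.

    Each replicate draws a fresh balanced negative subset (all positives kept)
    and is evaluated by stratified k-fold CV; the report aggregates the
    replicate-level metrics as mean +/- sd.  ``outer_repeats`` multiplies the
    number of replicates for users who want the heavier protocol.
    """
    total = n_replicates * outer_repeats
    replicates = make_balanced_replicates(sub, n_replicates=total, master_seed=seed)
    rows = []
    confusions = []
    curve_list = []
    for rep in replicates:
        fold_cms, oof_scores, oof_labels = cross_validate(
            rep.X, rep.y, spec, C, k=k, seed=rep.seed
        )
        cm = sum(fold_cms[1:], fold_cms[0])
        cur = curves(rep.y, oof_scores)
        row = metrics(cm)
        row["auROC"] = cur.auroc
        row["auPR"] = cur.aupr
        rows.append(row)
        confusions.append(cm)
        curve_list.append(cur)
    per_replicate = pd.DataFrame(rows, index=range(1, total + 1))[list(METRIC_NAMES)]
    return EvaluationReport(
        per_replicate=per_replicate, confusions=confusions, curve_list=curve_list
    )
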