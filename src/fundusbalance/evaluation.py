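"""K-fold cross-validation with rotating validation/test folds and
one-vs-rest metrics.

Folds are stratified by class.  Iteration i uses fold i as the test set
and fold (i+1) mod k as the validation set; every fold therefore serves
as the test set exactly once.  Per-class metrics (accuracy, F1,
sensitivity, specificity, AUC) follow the one-vs-rest construction and
are reported on the percent scale, aggregated as mean +/- standard
deviation over folds, with pointwise-interpolated ROC bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .corpus import CorpusManifest, ManifestError
from .labels import CLASSES

__all__ = [
    "FoldPlan",
    "make_folds",
    "confusion",
    "ovr_metrics",
    "auc_ovr",
    "FoldReport",
    "evaluate_predictions",
    "CVSummary",
    "aggregate",
    "roc_band",
]

METRICS = ("accuracy", "f1", "sensitivity", "specificity", "auc")


@dataclass
class FoldPlan:
    """Partition of a manifest into k folds plus per-iteration roles."""

    k: int
    ids: list[str]
    assignment: np.ndarray  # fold index per id

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in zip(self.ids, self.assignment) if f == fold]

    def iteration(self, i: int) -> tuple[list[str], list[str], list[str]]:
        """(test_ids, val_ids, train_ids) for CV iteration i."""
        test_f, val_f = i % self.k, (i + 1) % self.k
        test, val, train = [], [], []
        for rid, f in zip(self.ids, self.assignment):
            (test if f == test_f else val if f == val_f else train).append(rid)
        return test, val, train

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"id": self.ids, "fold": self.assignment}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FoldPlan":
        df = pd.read_csv(path)
        assignment = df["fold"].to_numpy()
        return cls(int(assignment.max()) + 1, [str(i) for i in df["id"]], assignment)


def make_folds(manifest: CorpusManifest, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified partition into k near-equal folds."""
    if k < 3:
        raise ValueError("k must be >= 3 (test, validation and training folds)")
    counts = manifest.counts
    for label, n in counts.items():
        if 0 < n < k:
            raise ManifestError(
                f"class {label} has only {n} records; stratified {k}-fold needs >= {k}"
            )
    labels = [r.label for r in manifest]
    ids = [r.id for r in manifest]
    assignment = np.empty(len(ids), dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    for f, (_, fold_idx) in enumerate(skf.split(np.zeros(len(ids)), labels)):
        assignment[fold_idx] = f
    return FoldPlan(k=k, ids=ids, assignment=assignment)


def confusion(
    predictions: Sequence[str], truths: Sequence[str], classes: Sequence[str] = CLASSES
) -> np.ndarray:
    """Confusion matrix with rows = true class, columns = predicted class."""
    if len(predictions) != len(truths) or len(truths) == 0:
        raise ValueError("predictions and truths must have equal nonzero length")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(predictions, truths):
        cm[index[t], index[p]] += 1
    return cm


def ovr_metrics(cm: np.ndarray, c: int) -> dict:
    """One-vs-rest accuracy, F1, sensitivity and specificity (percent) for class c.

    Degenerate 0/0 ratios are reported as 0 (sensitivity, F1) or 100
    (specificity) with the metric name recorded under ``degenerate``.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total < 1:
        raise ValueError("confusion matrix is empty")
    tp = cm[c, c]
    fn = cm[c].sum() - tp
    fp = cm[:, c].sum() - tp
    tn = total - tp - fn - fp
    degenerate = []

    if tp + fn == 0:
        sens = 0.0
        degenerate.append("sensitivity")
    else:
        sens = 100.0 * tp / (tp + fn)
    if tn + fp == 0:
        spec = 100.0
        degenerate.append("specificity")
    else:
        spec = 100.0 * tn / (tn + fp)
    if 2 * tp + fp + fn == 0:
        f1 = 0.0
        degenerate.append("f1")
    else:
        f1 = 100.0 * 2 * tp / (2 * tp + fp + fn)
    acc = 100.0 * (tp + tn) / total
    return {"accuracy": acc, "f1": f1, "sensitivity": sens, "specificity": spec,
            "degenerate": degenerate}


def auc_ovr(scores: Sequence[float], truths: Sequence[int]) -> float:
    """One-vs-rest AUC (percent) via the rank-sum statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    outscores the negative, ties counted half; identical to the
    trapezoidal area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths, dtype=int)
    n_pos = int(truths.sum())
    n_neg = len(truths) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both positive and negative samples")
    ranks = rankdata(scores)
    u = ranks[truths == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


@dataclass
class FoldReport:
    """Metrics of one CV iteration's test fold."""

    cm: np.ndarray
    per_class: dict[str, dict]            # class -> metric -> value
    macro: dict[str, float]               # metric -> unweighted class mean
    overall_accuracy: float
    roc: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def evaluate_predictions(
    probs: np.ndarray, truths: np.ndarray, classes: Sequence[str] = CLASSES
) -> FoldReport:
    """Build a FoldReport from softmax probabilities and integer truths."""
    probs = np.asarray(probs, dtype=float)
    truths = np.asarray(truths, dtype=int)
    preds = probs.argmax(axis=1)
    cm = confusion([classes[p] for p in preds], [classes[t] for t in truths], classes)
    per_class: dict[str, dict] = {}
    roc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, cname in enumerate(classes):
        m = ovr_metrics(cm, ci)
        binary = (truths == ci).astype(int)
        if 0 < binary.sum() < len(binary):
            m["auc"] = auc_ovr(probs[:, ci], binary)
            fpr, tpr, _ = roc_curve(binary, probs[:, ci])
            roc[cname] = (fpr, tpr)
        else:
            m["auc"] = 0.0
            m["degenerate"].append("auc")
        per_class[cname] = m
    macro = {met: float(np.mean([per_class[c][met] for c in classes])) for met in METRICS}
    overall = 100.0 * np.trace(cm) / cm.sum()
    return FoldReport(cm=cm, per_class=per_class, macro=macro,
                      overall_accuracy=float(overall), roc=roc)


@dataclass
class CVSummary:
    """Mean +/- std of every metric over the k fold reports."""

    k: int
    per_class: dict[str, dict[str, tuple[float, float]]]
    macro: dict[str, tuple[float, float]]
    overall_accuracy: tuple[float, float]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for cname, metrics in self.per_class.items():
            for met, (mean, std) in metrics.items():
                rows.append({"class": cname, "metric": met,
                             "value": f"{mean:.2f} ± {std:.2f}"})
        for met, (mean, std) in self.macro.items():
            rows.append({"class": "Average", "metric": met,
                         "value": f"{mean:.2f} ± {std:.2f}"})
        mean, std = self.overall_accuracy
        rows.append({"class": "Overall", "metric": "accuracy",
                     "value": f"{mean:.2f} ± {std:.2f}"})
        return pd.DataFrame(rows)


def aggregate(fold_reports: Sequence[FoldReport], ddof: int = 0) -> CVSummary:
    """Aggregate fold reports to mean +/- std per class and metric.

    The default standard deviation is the population convention
    (``ddof=0``), read as a descriptive statistic over the k folds.
    """
    if len(fold_reports) < 2:
        raise ValueError("aggregation needs at least 2 fold reports")
    class_sets = {tuple(sorted(r.per_class)) for r in fold_reports}
    if len(class_sets) != 1:
        raise ValueError("fold reports have inconsistent class sets")
    classes = list(fold_reports[0].per_class)

    def mean_std(values):
        a = np.asarray(values, dtype=float)
        return float(a.mean()), float(a.std(ddof=ddof))

    per_class = {
        c: {met: mean_std([r.per_class[c][met] for r in fold_reports]) for met in METRICS}
        for c in classes
    }
    macro = {met: mean_std([r.macro[met] for r in fold_reports]) for met in METRICS}
    overall = mean_std([r.overall_accuracy for r in fold_reports])
    return CVSummary(k=len(fold_reports), per_class=per_class,
                     macro=macro, overall_accuracy=overall)


def roc_band(
    curves: Sequence[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean ROC curve with a pointwise std band.

    Each fold's curve is linearly interpolated onto a fixed FPR grid;
    returns (fpr_grid, mean_tpr, std_tpr).  Std uses the population
    convention, matching :func:`aggregate`.
    """
    if len(curves) < 2:
        raise ValueError("a ROC band needs at least 2 curves")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = []
    for fpr, tpr in curves:
        fpr, tpr = np.asarray(fpr, dtype=float), np.asarray(tpr, dtype=float)
        if fpr.size < 2:
            raise ValueError("each ROC curve needs at least 2 points")
        tprs.append(np.interp(grid, fpr, tpr))
    tprs = np.stack(tprs)
    return grid, tprs.mean(axis=0), tprs.std(axis=0)
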