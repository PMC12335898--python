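"""Imbalance-aware evaluation: confusion matrices, per-class precision /
recall / F1, stratified cross-validation, and the k-grid model-selection
protocol.

Per-class metrics are derived one-vs-rest from the confusion matrix. A zero
denominator (no predicted or no true samples of a class) yields ``None``
rather than a coerced 0; macro averages skip undefined entries and report
how many were excluded. Class-specific F1 is the principal metric because
tissue-of-origin cohorts are heavily imbalanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_io import ExpressionTable, LabelTable
from . import pipeline as _pipeline


@dataclass
class ConfusionMatrix:
    class_labels: list[str]
    counts: np.ndarray  # rows = truth, columns = prediction

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.class_labels)
        if self.counts.shape != (c, c):
            raise ValueError("confusion matrix must be square over class_labels")
        if (self.counts < 0).any():
            raise ValueError("negative confusion counts")


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    f1: dict[str, float | None]
    macro_f1: float
    n_undefined_f1: int = 0


@dataclass
class CVResult:
    folds: int
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    pooled_confusion: ConfusionMatrix
    grid: dict[tuple[int, str], float] = field(default_factory=dict)
    selected: tuple[int, str] | None = None


def compute_metrics(
    truth: Sequence[str], predicted: Sequence[str]
) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion matrix plus accuracy and per-class one-vs-rest metrics.

    The label universe is the union of truth and predicted labels (sorted),
    so out-of-universe predictions show up as their own column rather than
    being silently dropped.
    """
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal length")
    labels = sorted(set(truth) | set(predicted))
    idx = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, predicted):
        counts[idx[t], idx[p]] += 1
    cm = ConfusionMatrix(labels, counts)
    total = counts.sum()
    accuracy = float(np.trace(counts) / total) if total else 0.0
    precision: dict[str, float | None] = {}
    recall: dict[str, float | None] = {}
    f1: dict[str, float | None] = {}
    for lab in labels:
        i = idx[lab]
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        precision[lab] = float(tp / (tp + fp)) if (tp + fp) else None
        recall[lab] = float(tp / (tp + fn)) if (tp + fn) else None
        if precision[lab] is None or recall[lab] is None or (precision[lab] + recall[lab]) == 0:
            f1[lab] = None if (precision[lab] is None or recall[lab] is None) else 0.0
        else:
            f1[lab] = 2 * precision[lab] * recall[lab] / (precision[lab] + recall[lab])
    defined = [v for v in f1.values() if v is not None]
    macro_f1 = float(np.mean(defined)) if defined else 0.0
    report = MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=macro_f1,
        n_undefined_f1=sum(v is None for v in f1.values()),
    )
    return cm, report


def stratified_folds(
    labels: LabelTable, folds: int, seed: int = 0
) -> dict[str, int]:
    """Deterministic stratified fold assignment, sample_id -> fold index.

    Per-class counts across folds differ by at most one. Classes with fewer
    samples than folds trigger a warning and best-effort assignment.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    sample_ids = labels.sample_ids
    if folds > len(sample_ids):
        raise ValueError("more folds than samples")
    y = np.array([labels.assignments[s] for s in sample_ids])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            for i in test_idx:
                assignment[sample_ids[i]] = fold
    return assignment


def _evaluate_fold(
    table: ExpressionTable,
    labels: LabelTable,
    train_samples: list[str],
    test_samples: list[str],
    k: int,
    classifier: str,
    seed: int,
    padj_cutoff: float | None,
    pairs_per_classifier: int,
) -> tuple[list[str], list[str]]:
    train_tab = table.subset_samples(train_samples)
    test_tab = table.subset_samples(test_samples)
    train_lab = LabelTable({s: labels.assignments[s] for s in train_samples})
    fitted = _pipeline.fit_pipeline(
        train_tab,
        train_lab,
        k=k,
        classifier=classifier,
        seed=seed,
        padj_cutoff=padj_cutoff,
        pairs_per_classifier=pairs_per_classifier,
    )
    pred = _pipeline.predict_pipeline(fitted, test_tab)
    return labels.labels_for(test_samples), pred.predicted_labels


def run_k_grid(
    table: ExpressionTable,
    labels: LabelTable,
    k_values: Sequence[int],
    classifiers: Sequence[str] = ("logreg",),
    folds: int = 5,
    seed: int = 0,
    padj_cutoff: float | None = 0.05,
    pairs_per_classifier: int = 5,
) -> CVResult:
    """Cross-validated (k, classifier) grid search.

    DE, panel construction and model fitting all happen inside each training
    fold; the held-out fold only ever passes through the fitted transform,
    so feature selection cannot leak test labels. Selection maximizes pooled
    accuracy, ties broken by smaller k then classifier name.
    """
    if not k_values:
        raise ValueError("k_values must be nonempty")
    missing = set(labels.sample_ids) ^ set(table.sample_ids)
    if missing:
        raise ValueError(f"sample mismatch between table and labels: {sorted(missing)[:5]}")
    fold_of = stratified_folds(labels, folds, seed)
    splits = []
    for f in range(folds):
        test = [s for s in table.sample_ids if fold_of[s] == f]
        train = [s for s in table.sample_ids if fold_of[s] != f]
        train_classes = {labels.assignments[s] for s in train}
        if train_classes != set(labels.class_labels):
            warnings.warn(f"fold {f}: training split is missing a class", stacklevel=2)
        splits.append((train, test))

    grid: dict[tuple[int, str], float] = {}
    per_combo: dict[tuple[int, str], tuple[list[MetricsReport], list[str], list[str]]] = {}
    for k in k_values:
        for clf in classifiers:
            fold_reports: list[MetricsReport] = []
            all_truth: list[str] = []
            all_pred: list[str] = []
            for f, (train, test) in enumerate(splits):
                truth, pred = _evaluate_fold(
                    table, labels, train, test, k, clf,
                    seed=seed + 1000 * f, padj_cutoff=padj_cutoff,
                    pairs_per_classifier=pairs_per_classifier,
                )
                _, rep = compute_metrics(truth, pred)
                fold_reports.append(rep)
                all_truth.extend(truth)
                all_pred.extend(pred)
            _, pooled = compute_metrics(all_truth, all_pred)
            grid[(k, clf)] = pooled.accuracy
            per_combo[(k, clf)] = (fold_reports, all_truth, all_pred)

    selected = min(grid, key=lambda kc: (-grid[kc], kc[0], kc[1]))
    fold_reports, all_truth, all_pred = per_combo[selected]
    pooled_cm, pooled = compute_metrics(all_truth, all_pred)
    return CVResult(
        folds=folds,
        fold_reports=fold_reports,
        pooled=pooled,
        pooled_confusion=pooled_cm,
        grid=grid,
        selected=selected,
    )


def metrics_payload(report: MetricsReport) -> dict:
    return {
        "accuracy": report.accuracy,
        "macro_f1": report.macro_f1,
        "n_undefined_f1": report.n_undefined_f1,
        "per_class": {
            lab: {
                "precision": report.precision[lab],
                "recall": report.recall[lab],
                "f1": report.f1[lab],
            }
            for lab in sorted(report.f1)
        },
    }
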