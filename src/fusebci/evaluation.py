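"""Cross-validated evaluation: folds, binary metrics, Friedman test.

All method arms are scored with stratified 5-fold cross-validation;
accuracy, precision, recall and F1 are computed from 2x2 confusion matrices
with the positive class fixed to ``left`` (class 0), and reported as
percent mean +- SD across folds/subjects.  The Friedman test compares the
cross-validated accuracies of several methods over the same subjects; folds
are computed once per subject per seed and shared across arms so the test
compares methods on identical partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import EvalReport, SubjectDataset, TrialSet, subset_trials

__all__ = [
    "FoldPlan",
    "BinaryMetrics",
    "FriedmanResult",
    "make_folds",
    "metrics_from_confusion",
    "confusion_from_predictions",
    "friedman_test",
    "evaluate_method",
    "METHOD_ARMS",
]

METHOD_ARMS = (
    "eeg_base",
    "fnirs_base",
    "linear_fusion_no_transfer",
    "ours",
    "coral_arm",
    "mmd_arm",
)


@dataclass(frozen=True)
class FoldPlan:
    """A deterministic stratified partition of trial indices."""

    k: int
    folds: tuple[tuple[int, ...], ...]
    stratified: bool
    seed: int

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.array(self.folds[fold], dtype=np.int64)
        train = np.array(
            [i for f, fold_idx in enumerate(self.folds) if f != fold
             for i in fold_idx], dtype=np.int64)
        return train, test


def make_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan; every fold contains both classes."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    for c in np.unique(labels):
        if (labels == c).sum() < k:
            raise ValueError(
                f"class {c} has fewer than k={k} trials; cannot stratify"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = tuple(tuple(int(i) for i in test)
                  for _, test in skf.split(np.zeros(len(labels)), labels))
    return FoldPlan(k=k, folds=folds, stratified=True, seed=seed)


@dataclass(frozen=True)
class BinaryMetrics:
    """Accuracy/precision/recall/F1 as fractions; ``degenerate`` flags a
    zero-denominator precision or recall (reported as 0)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    def __iter__(self):
        return iter((self.accuracy, self.precision, self.recall, self.f1))


def metrics_from_confusion(cm: np.ndarray) -> BinaryMetrics:
    """Standard binary metrics from a 2x2 confusion matrix.

    Rows are true class, columns predicted, in (left, right) order; the
    positive class is ``left`` (class 0).
    """
    cm = np.asarray(cm)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion matrix must be 2x2 with non-negative counts")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp, fn = cm[0, 0], cm[0, 1]
    fp, tn = cm[1, 0], cm[1, 1]
    acc = (tp + tn) / total
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BinaryMetrics(float(acc), float(precision), float(recall),
                         float(f1), degenerate)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((2, 2), dtype=np.int64)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[int(t), int(p)] += 1
    return cm


class FriedmanResult(NamedTuple):
    statistic: float
    p_value: float
    mean_ranks: np.ndarray  # per method (column)


def friedman_test(acc: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a subjects x methods accuracy matrix.

    Returns the chi-square statistic, its p-value and the per-method mean
    rank (rank 1 = worst accuracy).  If every subject ranks all methods
    identically (all rows constant) the statistic is 0 with p = 1.
    """
    acc = np.asarray(acc, dtype=np.float64)
    if acc.ndim != 2 or acc.shape[0] < 2 or acc.shape[1] < 2:
        raise ValueError("need >= 2 subjects (rows) and >= 2 methods (columns)")
    if not np.isfinite(acc).all():
        raise ValueError("missing cells in the accuracy matrix")
    ranks = np.vstack([sps.rankdata(row) for row in acc])
    mean_ranks = ranks.mean(axis=0)
    if all(np.ptp(row) == 0 for row in acc):
        return FriedmanResult(0.0, 1.0, mean_ranks)
    stat, p = sps.friedmanchisquare(*[acc[:, j] for j in range(acc.shape[1])])
    return FriedmanResult(float(stat), float(p), mean_ranks)


# ---------------------------------------------------------------------------
# Method-arm evaluation


def _report_from_folds(method: str, subject_id: str, cms: list[np.ndarray]) -> EvalReport:
    per_fold = [metrics_from_confusion(cm) for cm in cms]
    return EvalReport(
        method_label=method,
        subject_id=subject_id,
        fold_accuracy=np.array([m.accuracy for m in per_fold]),
        fold_precision=np.array([m.precision for m in per_fold]),
        fold_recall=np.array([m.recall for m in per_fold]),
        fold_f1=np.array([m.f1 for m in per_fold]),
        confusion_matrix=np.sum(cms, axis=0),
    )


def _eval_single_modality(sd: SubjectDataset, modality: str, spec, plan: FoldPlan,
                          epochs: int, seed: int, batch_size: int) -> EvalReport:
    from .base_networks import build_base_model, split_train_val, train_base

    ts: TrialSet = getattr(sd, modality)
    cms = []
    for fold in range(plan.k):
        tr_idx, te_idx = plan.train_test(fold)
        tr = subset_trials(ts, tr_idx)
        te = subset_trials(ts, te_idx)
        model = build_base_model(spec, seed=seed + 17 * fold)
        inner_tr, inner_val = split_train_val(tr, seed=seed + 17 * fold)
        train_base(model, inner_tr, inner_val, epochs=epochs, seed=seed + 17 * fold,
                   batch_size=batch_size)
        cms.append(confusion_from_predictions(te.labels, model.predict(te.data)))
    return _report_from_folds(f"{modality}_base", sd.subject_id, cms)


def evaluate_method(
    population: list[SubjectDataset],
    method: str,
    specs: dict | None = None,
    epochs: int = 30,
    transfer_epochs: int = 20,
    batch_size: int = 16,
    k_folds: int = 5,
    seed: int = 0,
    pretrained: dict | None = None,
    folds: dict | None = None,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """Cross-validated metrics of one method arm over a population.

    Returns ``(per-subject EvalReports, pooled summary frame)``.  For the
    transfer arms the optimal source subjects are selected per modality via
    trusted scores and the remaining subjects are evaluated as targets;
    ``pretrained`` (from :func:`fusebci.fusion_training.pretrain_population`)
    avoids re-training base models across arms, and ``folds`` shares the
    per-subject fold plans so every arm is compared on identical partitions.
    """
    from .base_networks import NetworkSpec
    from . import fusion_training as ft

    if method not in METHOD_ARMS:
        raise ValueError(f"unknown method {method!r}; valid arms: {METHOD_ARMS}")
    if specs is None:
        specs = {
            "eeg": NetworkSpec.eeg_default(),
            "fnirs": NetworkSpec.fnirs_default(),
        }
    if folds is None:
        folds = {sd.subject_id: make_folds(sd.eeg.labels, k=k_folds, seed=seed)
                 for sd in population}

    reports: dict[str, EvalReport] = {}
    if method in ("eeg_base", "fnirs_base"):
        modality = method.split("_")[0]
        for sd in population:
            reports[sd.subject_id] = _eval_single_modality(
                sd, modality, specs[modality], folds[sd.subject_id],
                epochs, seed, batch_size)
    elif method == "linear_fusion_no_transfer":
        for sd in population:
            reports[sd.subject_id] = ft.evaluate_fusion_no_transfer(
                sd, specs, folds[sd.subject_id], epochs=transfer_epochs,
                batch_size=batch_size, seed=seed)
    else:
        if pretrained is None:
            pretrained = ft.pretrain_population(
                population, specs, epochs=epochs, batch_size=batch_size, seed=seed)
        arm = {"ours": "ours", "coral_arm": "coral", "mmd_arm": "mmd"}[method]
        sel = ft.select_sources(population, pretrained, source_mode="separate")
        sources = {sel.eeg_source, sel.fnirs_source}
        for sd in population:
            if sd.subject_id in sources:
                continue
            cfg = ft.TransferRunConfig(
                source_eeg=sel.eeg_source, source_fnirs=sel.fnirs_source,
                target=sd.subject_id, epochs=transfer_epochs,
                batch_size=batch_size, seed=seed, k_folds=k_folds,
                loss=ft.TransferLossConfig(arm=arm),
            )
            _, rep = ft.train_transfer(population, cfg, pretrained, specs,
                                       plan=folds[sd.subject_id])
            rep.method_label = method
            reports[sd.subject_id] = rep

    rows = []
    for sid, rep in reports.items():
        rows.append({
            "subject_id": sid,
            "method": method,
            "accuracy": rep.accuracy,
            "precision": float(np.mean(rep.fold_precision)),
            "recall": float(np.mean(rep.fold_recall)),
            "f1": float(np.mean(rep.fold_f1)),
        })
    frame = pd.DataFrame(rows)
    return reports, frame


def summary_percent(frame: pd.DataFrame) -> dict[str, str]:
    """Mean +- SD across subjects, percent scale, two decimals."""
    out = {"method": frame["method"].iloc[0]}
    for col in ("accuracy", "precision", "recall", "f1"):
        vals = 100 * frame[col].to_numpy()
        sd = np.std(vals, ddof=1) if len(vals) > 1 else 0.0
        out[col] = f"{vals.mean():.2f} ± {sd:.2f}"
    return out
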