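"""Confusion-matrix metrics, ROC/AUC and the cross-validation protocol.

The positive class (label 1) is the enzyme class throughout.  Metrics follow
the standard definitions:

    sensitivity = TP / (TP + FN)          specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any factor of the denominator vanishes.  ROC
curves and stratified fold assignment are delegated to scikit-learn; the
evaluation protocol (stratified independent hold-out first, then k-fold
cross-validation on the remainder, out-of-fold pooling) is implemented here.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from ddecnn.cnn import (
    ArchitectureSpec,
    TrainedModel,
    TrainingConfig,
    build_model,
    train,
)
from ddecnn.dde import Denominator, dde_vector, to_network_tensor
from ddecnn.errors import LeakageError
from ddecnn.sequence_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    """Metrics of one fold or of the independent set at a fixed threshold."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float
    threshold: float
    roc_points: tuple = field(default=(), repr=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("roc_points")
        d["counts"] = dataclasses.asdict(self.counts)
        return d


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per sample for stratified k-fold cross-validation."""

    fold_index: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.fold_index, dtype=np.int64)
        object.__setattr__(self, "fold_index", idx)
        if idx.min() < 0 or idx.max() >= self.k:
            raise ValueError("fold indices outside [0, k)")


def _binary(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0 and 1")
    return a


def confusion(labels, predictions) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with 1 = enzyme (positive class)."""
    y = _binary(labels, "labels")
    p = _binary(predictions, "predictions")
    if len(y) != len(p):
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(((y == 1) & (p == 1)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise ZeroDivisionError("sensitivity undefined: no positive samples")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise ZeroDivisionError("specificity undefined: no negative samples")
    return c.tn / (c.tn + c.fp)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ZeroDivisionError("accuracy undefined: no samples")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def roc_auc(scores, labels) -> tuple[float, list[tuple[float, float, float]]]:
    """AUC plus the ROC point list [(threshold, fpr, tpr), ...].

    AUC equals the probability that a random positive outscores a random
    negative, ties counting one half (trapezoidal integration over the
    threshold sweep).
    """
    y = _binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("ROC AUC requires both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, list(zip(thr.tolist(), fpr.tolist(), tpr.tolist()))


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity - 1 (Youden's J)."""
    _, points = roc_auc(scores, labels)
    best = max(points, key=lambda p: p[2] - p[1])
    return float(best[0])


def evaluate_scores(
    labels,
    scores,
    threshold: float | str = 0.5,
) -> EvaluationReport:
    """Binarize positive-class scores and report the full metric suite.

    ``threshold`` may be a float or ``"youden"`` (the point of the ROC curve
    balancing sensitivity against specificity).
    """
    y = _binary(labels, "labels")
    s = np.asarray(scores, dtype=np.float64)
    auc, points = roc_auc(s, y)
    thr = youden_threshold(s, y) if threshold == "youden" else float(threshold)
    c = confusion(y, (s >= thr).astype(int))
    return EvaluationReport(
        counts=c,
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        accuracy=accuracy(c),
        mcc=mcc(c),
        auc=auc,
        threshold=thr,
        roc_points=tuple(points),
    )


def stratified_k_fold(labels, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified fold assignment; per-class counts differ <= 1."""
    y = _binary(labels, "labels")
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(len(y), dtype=np.int64)
    for f, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        fold_index[test_idx] = f
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


def independent_holdout_split(
    labels,
    seed: int = 0,
    pos_fraction: float = 129 / 652,
    neg_fraction: float = 249 / 1108,
) -> np.ndarray:
    """Boolean mask of the stratified independent hold-out set.

    Default per-class fractions reproduce, at the default benchmark sizes of
    652 positives and 1,108 negatives, an independent set of exactly 129
    positives and 249 negatives; the remainder is the cross-validation pool.
    """
    y = _binary(labels, "labels")
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(y), dtype=bool)
    for cls, frac in ((1, pos_fraction), (0, neg_fraction)):
        idx = np.flatnonzero(y == cls)
        n_hold = int(round(frac * len(idx)))
        mask[rng.choice(idx, size=n_hold, replace=False)] = True
    logger.info(
        "independent hold-out: %d positives, %d negatives",
        int((y[mask] == 1).sum()), int((y[mask] == 0).sum()),
    )
    return mask


def _featurize(records: Sequence[ProteinRecord], denominator: Denominator) -> np.ndarray:
    return np.stack([
        to_network_tensor(dde_vector(r.sequence, r.id, denominator=denominator))
        for r in records
    ])


def cross_validate(
    records: Sequence[ProteinRecord],
    labels,
    spec: ArchitectureSpec | None = None,
    config: TrainingConfig | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float | str = 0.5,
    denominator: Denominator = "sqrt",
) -> dict:
    """Stratified k-fold cross-validation of the full pipeline.

    Each fold's model is trained only on the other k-1 folds; the pooled
    report is computed from the concatenated out-of-fold predictions, which
    cover every sample exactly once.  Returns a dict with ``fold_reports``,
    ``pooled``, ``fold_assignment`` and the out-of-fold ``scores``.
    """
    y = _binary(labels, "labels")
    records = list(records)
    if len(records) != len(y):
        raise ValueError("records and labels must have equal length")
    spec = spec or ArchitectureSpec()
    config = config or TrainingConfig(seed=seed)
    x = _featurize(records, denominator)
    assignment = stratified_k_fold(y, k=k, seed=seed)
    oof_scores = np.full(len(y), np.nan)
    fold_reports: list[EvaluationReport] = []
    for f in range(k):
        test = assignment.fold_index == f
        fold_cfg = dataclasses.replace(config, seed=config.seed + f)
        model = build_model(spec, fold_cfg)
        trained = train(
            model, x[~test], y[~test],
            train_ids=[records[i].id for i in np.flatnonzero(~test)],
            feature_meta={"denominator": denominator},
        )
        scores = trained.model.predict_proba(x[test])[:, 1]
        oof_scores[test] = scores
        fold_reports.append(evaluate_scores(y[test], scores, threshold))
        logger.info("fold %d/%d: acc=%.4f auc=%.4f", f + 1, k,
                    fold_reports[-1].accuracy, fold_reports[-1].auc)
    assert not np.isnan(oof_scores).any()
    pooled = evaluate_scores(y, oof_scores, threshold)
    return {
        "fold_reports": fold_reports,
        "pooled": pooled,
        "fold_assignment": assignment,
        "scores": oof_scores,
    }


def independent_eval(
    trained: TrainedModel,
    records: Sequence[ProteinRecord],
    labels,
    threshold: float | str = 0.5,
) -> EvaluationReport:
    """Evaluate on a held-out set at the given threshold with a leakage guard.

    If the trained model recorded its training ids, any overlap with the
    held-out ids raises :class:`LeakageError`.
    """
    y = _binary(labels, "labels")
    records = list(records)
    if trained.train_ids is not None:
        overlap = {r.id for r in records} & set(trained.train_ids)
        if overlap:
            raise LeakageError(
                f"{len(overlap)} held-out id(s) were used for training, "
                f"e.g. {sorted(overlap)[:3]}"
            )
    denominator = trained.feature_meta.get("denominator", "sqrt")
    scores = trained.model.predict_proba(_featurize(records, denominator))[:, 1]
    return evaluate_scores(y, scores, threshold)
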