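"""Confusion-matrix metrics, ROC/AUC, stratified k-fold CV and the
train / independent-test protocol.

ACC = (TP+TN)/total, SN = TP/(TP+FN), SP = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
F1 = 2TP/(2TP+FP+FN); any zero denominator defines that metric as 0.
AUC is the Mann-Whitney rank statistic with midranks for ties.

Cross-validation uses stratified folds (class imbalance makes unstratified
folds noisy at a few hundred samples) and reports per-fold metrics plus
their fold average; a pooled-count variant is available behind a flag.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .hdnet import CascadeConfig, fit_cascade, predict, predict_proba

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "metrics",
    "roc_auc",
    "kfold_cv",
    "independent_test",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class EvalReport:
    """Threshold metrics plus AUC; ``per_fold`` holds fold reports for CV."""

    acc: float
    sn: float
    sp: float
    mcc: float
    f1: float
    auc: float | None = None
    per_fold: list["EvalReport"] | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("acc", "sn", "sp", "mcc", "f1", "auc")}
        if self.per_fold is not None:
            d["per_fold"] = [f.to_dict() for f in self.per_fold]
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        parts = [
            f"ACC={self.acc:.4f}",
            f"SN={self.sn:.4f}",
            f"SP={self.sp:.4f}",
            f"MCC={self.mcc:.4f}",
            f"F1={self.f1:.4f}",
        ]
        if self.auc is not None:
            parts.append(f"AUC={self.auc:.4f}")
        return "  ".join(parts)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics(c: ConfusionCounts) -> EvalReport:
    """Threshold-dependent metrics with the zero-denominator-is-0 convention."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return EvalReport(
        acc=(tp + tn) / c.total,
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        mcc=_ratio(tp * tn - fp * fn, mcc_den),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def roc_auc(scores, labels) -> float:
    """AUC of positive-class scores (midrank/Mann-Whitney convention)."""
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _evaluate_predictions(y_true, y_pred, scores) -> EvalReport:
    report = metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    # AUC is undefined on a single-class set (e.g. a leave-one-out fold)
    report.auc = (
        roc_auc(scores, y_true) if np.unique(np.asarray(y_true)).size == 2 else None
    )
    return report


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    config: CascadeConfig | None = None,
    pooled: bool = False,
) -> EvalReport:
    """Stratified k-fold cross-validation of the cascade.

    Per fold: fit on k-1 folds, evaluate on the held-out fold. The headline
    report averages metrics over folds; ``pooled=True`` instead computes the
    threshold metrics from the pooled confusion counts (AUC is always pooled
    over the out-of-fold scores in that mode).
    """
    if config is None:
        config = CascadeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    class_counts = np.bincount(y, minlength=2)
    if k == len(y):
        # leave-one-out boundary: single-sample folds cannot be stratified
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    elif class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} members; cannot make {k} folds"
        )
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)
    fold_reports: list[EvalReport] = []
    oof_pred = np.empty_like(y)
    oof_score = np.empty(len(y), dtype=float)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        cfg = dataclasses.replace(config, seed=int(fold_seeds[fold]))
        model = fit_cascade(X[train_idx], y[train_idx], cfg)
        proba = predict_proba(model, X[test_idx])
        pred = (proba[:, 1] >= proba[:, 0]).astype(int)
        oof_pred[test_idx] = pred
        oof_score[test_idx] = proba[:, 1]
        fold_reports.append(_evaluate_predictions(y[test_idx], pred, proba[:, 1]))
    if pooled:
        summary = _evaluate_predictions(y, oof_pred, oof_score)
    else:
        aucs = [r.auc for r in fold_reports if r.auc is not None]
        summary = EvalReport(
            acc=float(np.mean([r.acc for r in fold_reports])),
            sn=float(np.mean([r.sn for r in fold_reports])),
            sp=float(np.mean([r.sp for r in fold_reports])),
            mcc=float(np.mean([r.mcc for r in fold_reports])),
            f1=float(np.mean([r.f1 for r in fold_reports])),
            auc=float(np.mean(aucs)) if aucs else None,
        )
    summary.per_fold = fold_reports
    return summary


def independent_test(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: CascadeConfig | None = None,
    train_ids: list[str] | None = None,
    test_ids: list[str] | None = None,
    allow_overlap: bool = False,
) -> EvalReport:
    """Fit once on the training set, evaluate once on the held-out set.

    If ids are given the two sets must be disjoint (``allow_overlap=True``
    bypasses the check for resubstitution smoke tests only).
    """
    if train_ids is not None and test_ids is not None and not allow_overlap:
        overlap = sorted(set(train_ids) & set(test_ids))
        if overlap:
            raise ValueError(
                f"train/test ids overlap: {', '.join(overlap[:10])}"
                + ("..." if len(overlap) > 10 else "")
            )
    if config is None:
        config = CascadeConfig()
    model = fit_cascade(np.asarray(X_train, float), np.asarray(y_train, int), config)
    proba = predict_proba(model, np.asarray(X_test, float))
    pred = (proba[:, 1] >= proba[:, 0]).astype(int)
    return _evaluate_predictions(np.asarray(y_test, int), pred, proba[:, 1])
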