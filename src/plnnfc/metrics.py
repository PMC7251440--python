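"""Classification metrics and stratified cross-validation.

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/n, F1 = 2TP/(2TP+FP+FN); the positive class is the
patient group (label 1).  AUC is the area under the ROC curve (equivalently
the Mann-Whitney probability that a random positive outscores a random
negative, ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import ModelConfig, TrainedModel, forward, train

__all__ = ["MetricsReport", "evaluate", "cross_validate", "CVResult"]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def evaluate(
    pred_probs: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Confusion counts and derived metrics at the given probability threshold.

    If only one class is present AUC is undefined and reported as ``None``;
    the thresholded metrics are still computed.
    """
    p = np.asarray(pred_probs, dtype=float).ravel()
    y = np.asarray(labels, dtype=int).ravel()
    if p.size != y.size:
        raise ValueError("pred_probs and labels must have equal length")
    if not np.isin(y, [0, 1]).all():
        raise ValueError("labels must be binary")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    auc = float(roc_auc_score(y, p)) if np.unique(y).size == 2 else None
    return MetricsReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        accuracy=_safe_div(tp + tn, tp + fp + tn + fn),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        auc=auc,
    )


@dataclass
class CVResult:
    """Per-fold reports plus pooled held-out predictions (one per subject)."""

    fold_reports: list[MetricsReport]
    fold_models: list[TrainedModel]
    test_indices: list[np.ndarray]
    oof_probs: np.ndarray  # out-of-fold probability per subject

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean +/- std over folds for each metric."""
        out = {}
        for m in ("sensitivity", "specificity", "accuracy", "f1", "auc"):
            vals = [getattr(r, m) for r in self.fold_reports]
            vals = [v for v in vals if v is not None]
            out[m] = (float(np.mean(vals)), float(np.std(vals)))
        return out


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV: train one model per fold, score its held-out fold.

    The fold assignment and every per-fold training run are deterministic
    under ``seed``.  Held-out probabilities are pooled so each subject is
    interpreted exactly once, by the model that never saw it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    if X.shape[0] < k:
        raise ValueError(f"n={X.shape[0]} < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, models, test_idx = [], [], []
    oof = np.full(X.shape[0], np.nan)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        cfg = ModelConfig(**{**config.__dict__, "seed": (seed * 1000 + fold) % (2**31)})
        m = train(X[tr], y[tr], cfg)
        probs = forward(m, X[te])
        oof[te] = probs
        reports.append(evaluate(probs, y[te]))
        models.append(m)
        test_idx.append(te)
    return CVResult(reports, models, test_idx, oof)
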