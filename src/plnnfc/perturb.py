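"""Perturbation ("hacking") evaluation of decision features.

Zero out a chosen feature set in every instance (in Fisher-z space, so zero
means "no connectivity"), push the hacked instances back through the model,
and measure how much the prediction moved: CPP is the mean absolute change
in predicted positive-class probability, NLCI the number of instances whose
thresholded label flips.  If the mined decision features really carry the
model's decision, hacking them should move predictions far more than
hacking random feature sets of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .metrics import MetricsReport, evaluate
from .model import TrainedModel, forward

__all__ = ["HackReport", "hack_instances", "cpp_nlci", "svm_topweight_baseline", "random_set_cpp"]


@dataclass
class HackReport:
    feature_set_size: int
    mean_cpp: float
    nlci: int
    post_sensitivity: float
    post_accuracy: float
    per_instance_cpp: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["per_instance_cpp"] is not None:
            d["per_instance_cpp"] = [float(v) for v in d["per_instance_cpp"]]
        return d


def hack_instances(X: np.ndarray, features: Sequence[int]) -> np.ndarray:
    """Copy of X with the listed feature columns set to zero."""
    X = np.asarray(X, dtype=float)
    features = np.asarray(list(features), dtype=int)
    if features.size and (features.min() < 0 or features.max() >= X.shape[1]):
        raise IndexError("feature index out of range")
    Xh = X.copy()
    Xh[:, features] = 0.0
    return Xh


def _report(probs, probs_hacked, labels, n_features) -> HackReport:
    cpp = np.abs(probs - probs_hacked)
    flips = int(np.sum((probs >= 0.5) != (probs_hacked >= 0.5)))
    post = evaluate(probs_hacked, labels)
    return HackReport(
        feature_set_size=int(n_features),
        mean_cpp=float(cpp.mean()),
        nlci=flips,
        post_sensitivity=post.sensitivity,
        post_accuracy=post.accuracy,
        per_instance_cpp=cpp,
    )


def cpp_nlci(
    model: TrainedModel,
    X: np.ndarray,
    features: Sequence[int],
    labels: np.ndarray,
) -> HackReport:
    """Hack the network: zero the features, re-run the full eval-mode forward
    pass (activation patterns are recomputed — the hacked instance may land
    in a different linear region) and compare predictions."""
    probs = forward(model, X)
    probs_hacked = forward(model, hack_instances(X, features))
    return _report(probs, probs_hacked, np.asarray(labels), len(list(features)))


def svm_topweight_baseline(
    X: np.ndarray, y: np.ndarray, N: int, C: float = 1.0
) -> tuple[np.ndarray, HackReport, SVC]:
    """Linear-SVM control: rank features by |coefficient|, zero the top N,
    and re-score the SVM itself on the hacked inputs.

    Returns (feature indices, hack report, fitted SVM).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int).ravel()
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    coef = svm.coef_.ravel()
    order = np.lexsort((np.arange(coef.size), -np.abs(coef)))
    feats = np.sort(order[: max(0, min(N, coef.size))])

    def probs_of(M):
        # Platt scaling is stochastic; a logistic squash of the margin is a
        # deterministic monotone stand-in adequate for CPP/NLCI
        from scipy.special import expit

        return expit(svm.decision_function(M))

    probs = probs_of(X)
    probs_hacked = probs_of(hack_instances(X, feats))
    return feats, _report(probs, probs_hacked, y, feats.size), svm


def random_set_cpp(
    model: TrainedModel,
    X: np.ndarray,
    labels: np.ndarray,
    set_size: int,
    n_draws: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Mean CPP for ``n_draws`` random feature sets of the given size —
    the calibration control the decision features must beat."""
    rng = np.random.default_rng(seed)
    d = np.asarray(X).shape[1]
    out = np.empty(n_draws)
    for i in range(n_draws):
        feats = rng.choice(d, size=min(set_size, d), replace=False)
        out[i] = cpp_nlci(model, X, feats, labels).mean_cpp
    return out
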