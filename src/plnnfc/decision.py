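"""Group-level decision-feature mining from per-instance linear weights.

For each interpreted instance take the K features with the largest weight
(by magnitude by default), count how often each feature appears across
instances, and keep the features whose occurrence fraction reaches the
threshold epsilon.  The surviving set is the model's group-level "decision
feature set": the edges the classifier leans on consistently, not just for
one subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .linearize import LocalLinearModel

__all__ = ["DecisionFeatureSet", "top_k_features", "decision_feature_set", "sweep"]

Ranking = Literal["abs", "signed"]


@dataclass
class DecisionFeatureSet:
    K: int
    epsilon: float
    features: np.ndarray  # sorted unique feature indices
    counts: np.ndarray  # occurrence count per surviving feature
    n_instances: int

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_instances

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.features, "n_f": self.counts, "fraction": self.fractions}
        )


def _weights(llm: LocalLinearModel | np.ndarray) -> np.ndarray:
    return llm.w_hat if isinstance(llm, LocalLinearModel) else np.asarray(llm, dtype=float)


def top_k_features(
    llm: LocalLinearModel | np.ndarray, K: int, ranking: Ranking = "abs"
) -> np.ndarray:
    """Indices of the K top-weighted features for one instance.

    ``abs`` ranks by |w| (default: large negative weights argue for the
    control group and are just as decision-relevant); ``signed`` ranks by w
    descending.  Ties break toward the lower feature index.  Returns
    min(K, d) indices.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    w = _weights(llm)
    key = np.abs(w) if ranking == "abs" else w
    order = np.lexsort((np.arange(w.size), -key))
    return np.sort(order[: min(K, w.size)])


def decision_feature_set(
    llms: Sequence[LocalLinearModel | np.ndarray],
    K: int,
    epsilon: float,
    ranking: Ranking = "abs",
) -> DecisionFeatureSet:
    """Features present in at least a fraction epsilon of instance top-K sets."""
    if len(llms) == 0:
        raise ValueError("empty instance list")
    if not 0.0 < epsilon <= 1.0:
        raise ValueError("epsilon must be in (0, 1]")
    d = _weights(llms[0]).size
    counts = np.zeros(d, dtype=int)
    for llm in llms:
        counts[top_k_features(llm, K, ranking)] += 1
    n = len(llms)
    keep = np.flatnonzero(counts / n >= epsilon)
    return DecisionFeatureSet(
        K=K, epsilon=epsilon, features=keep, counts=counts[keep], n_instances=n
    )


def sweep(
    llms: Sequence[LocalLinearModel | np.ndarray],
    K_grid: Iterable[int],
    epsilon_grid: Iterable[float],
    ranking: Ranking = "abs",
) -> pd.DataFrame:
    """|F| over the full (K, epsilon) cross-product.

    |F| is nondecreasing in K (top-K sets are nested) and nonincreasing in
    epsilon (a stricter occurrence threshold keeps fewer features).
    """
    K_grid = list(K_grid)
    epsilon_grid = list(epsilon_grid)
    if not K_grid or not epsilon_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    n = len(llms)
    d = _weights(llms[0]).size
    for K in K_grid:
        counts = np.zeros(d, dtype=int)
        for llm in llms:
            counts[top_k_features(llm, K, ranking)] += 1
        frac = counts / n
        for eps in epsilon_grid:
            rows.append({"K": K, "epsilon": eps, "n_features": int(np.sum(frac >= eps))})
    return pd.DataFrame(rows)
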