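"""Group-level statistics of selected connectivity features.

For each decision feature: mean connectivity in each group, the mean
difference, and an independent two-sample t test (Welch by default; the
pooled-variance variant is available).  Means can be reported on the
Fisher-z scale the model sees or back-transformed to correlation units via
tanh before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import EdgeIndexMap, LabeledDataset

__all__ = ["group_stats", "significance_summary"]


@dataclass
class GroupStatsRow:
    k: int
    roi_i: int
    roi_j: int
    mean_pos: float
    mean_neg: float
    mean_diff: float
    t_stat: float
    p_value: float


def group_stats(
    dataset: LabeledDataset,
    features: Sequence[int],
    scale: Literal["z", "r"] = "z",
    equal_var: bool = False,
    index_map: EdgeIndexMap | None = None,
) -> pd.DataFrame:
    """One row per feature: group means, difference, t statistic, two-sided p.

    ``scale='r'`` back-transforms each subject's Fisher-z value with tanh
    before averaging and testing, so means are in correlation units.
    """
    feats = np.asarray(list(features), dtype=int)
    if feats.size == 0:
        raise ValueError("empty feature set")
    pos = dataset.X[dataset.y == 1][:, feats]
    neg = dataset.X[dataset.y == 0][:, feats]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects for a t test")
    if scale == "r":
        pos, neg = np.tanh(pos), np.tanh(neg)
    t, p = stats.ttest_ind(pos, neg, axis=0, equal_var=equal_var)
    imap = index_map or EdgeIndexMap(dataset.p)
    pairs = [imap.pair(int(k)) for k in feats]
    return pd.DataFrame(
        {
            "k": feats,
            "roi_i": [pr[0] for pr in pairs],
            "roi_j": [pr[1] for pr in pairs],
            "mean_pos": pos.mean(axis=0),
            "mean_neg": neg.mean(axis=0),
            "mean_diff": pos.mean(axis=0) - neg.mean(axis=0),
            "t_stat": t,
            "p_value": p,
        }
    )


def significance_summary(
    rows: pd.DataFrame, alpha: float = 0.05, correct: bool = False
) -> dict:
    """Count significant vs non-significant features at level alpha.

    No multiplicity correction by default; ``correct=True`` applies
    Benjamini-Hochberg and counts on the adjusted p values (recommended when
    the feature set is large).
    """
    if rows.empty:
        raise ValueError("no rows")
    p = rows["p_value"].to_numpy()
    if correct:
        from statsmodels.stats.multitest import multipletests

        p = multipletests(p, alpha=alpha, method="fdr_bh")[1]
    sig = int(np.sum(p < alpha))
    return {"n_significant": sig, "n_not_significant": int(p.size - sig), "alpha": alpha,
            "corrected": correct}
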