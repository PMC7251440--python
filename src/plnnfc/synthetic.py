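"""Synthetic two-group ROI time-series cohorts with planted connectivity edges.

Both groups share a low-rank-plus-diagonal base correlation structure
(latent "networks" driving several regions at once, as in real
resting-state data).  The patient group's target correlation is shifted by
``delta`` on a small planted edge set, then repaired to the nearest valid
correlation matrix by eigenvalue clipping.  Each subject receives a jittered
copy of their group's target and contributes T temporally independent
Gaussian samples, so the empirical Pearson matrix concentrates around the
target as T grows.

The planted edge indices are exposed (:func:`planted_truth`) so feature
recovery by the classifier + interpretation pipeline can be scored against
ground truth.

What this emulates — and what it does not: group-specific correlation
structure with subject variability, but no BOLD autocorrelation (an AR(1)
option adds temporal smoothness), no scanner/site effects, and no
heavy-tailed motion artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import EdgeIndexMap, LabeledDataset, RoiTimeSeries, build_dataset

__all__ = ["CohortSpec", "build_group_correlation", "sample_cohort", "planted_truth", "simulate_dataset"]


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults give the scaled-down test cohort: 20 ROIs, 200 subjects per
    group, 150 timepoints, 5 planted edges shifted by +0.3 correlation in
    the patient group, mild subject-level jitter.
    """

    p: int = 20
    n_per_group: int = 200
    T: int = 150
    planted_edges: list[tuple[int, int]] | None = None
    delta: float = 0.3
    n_factors: int = 3
    factor_strength: float = 0.35
    subject_jitter: float = 0.05
    ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_edges is None:
            # up to 5 disjoint ROI pairs, as many as the parcellation allows
            self.planted_edges = [(2 * i, 2 * i + 1) for i in range(min(5, self.p // 2))]
        for (i, j) in self.planted_edges:
            if not (0 <= i < j < self.p):
                raise ValueError(f"planted edge ({i},{j}) invalid for p={self.p}")
        if self.T < 3 or self.p < 2 or self.n_per_group < 1:
            raise ValueError("invalid cohort dimensions")


def _nearest_correlation(S: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Deterministic positive-definite repair: symmetrize, clip eigenvalues
    at ``eig_floor``, renormalize to unit diagonal."""
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, eig_floor, None)
    S = vecs @ np.diag(vals) @ vecs.T
    dinv = 1.0 / np.sqrt(np.diag(S))
    S = S * np.outer(dinv, dinv)
    np.fill_diagonal(S, 1.0)
    return (S + S.T) / 2.0


def build_group_correlation(spec: CohortSpec, group: str) -> np.ndarray:
    """Target correlation matrix for 'hc' (base) or 'asd' (base + planted shift).

    The base is low-rank latent factors plus independent noise, normalized
    to a correlation matrix; the patient target shifts planted edges by
    +delta and is PD-repaired.  The repair must leave non-planted entries
    essentially untouched (within delta/10), else an error is raised —
    a sign the requested shift is too aggressive for this base structure.
    """
    if group not in ("asd", "hc"):
        raise ValueError("group must be 'asd' or 'hc'")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    L = rng.normal(0.0, 1.0, size=(spec.p, spec.n_factors))
    cov = spec.factor_strength * (L @ L.T) / spec.n_factors + np.eye(spec.p)
    dinv = 1.0 / np.sqrt(np.diag(cov))
    base = _nearest_correlation(cov * np.outer(dinv, dinv))
    if group == "hc":
        return base
    target = base.copy()
    for (i, j) in spec.planted_edges:
        shifted = np.clip(target[i, j] + spec.delta, -0.99, 0.99)
        target[i, j] = target[j, i] = shifted
    repaired = _nearest_correlation(target)
    mask = np.ones_like(target, dtype=bool)
    np.fill_diagonal(mask, False)
    for (i, j) in spec.planted_edges:
        mask[i, j] = mask[j, i] = False
    drift = np.max(np.abs(repaired[mask] - base[mask])) if mask.any() else 0.0
    if drift > max(spec.delta / 10.0, 1e-8):
        raise RuntimeError(
            f"PD repair moved non-planted edges by {drift:.3f} (> delta/10); "
            "use a smaller delta or weaker factors"
        )
    return repaired


def _sample_subject(rng, target: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """T x p Gaussian series with a jittered copy of the group correlation."""
    p = spec.p
    if spec.subject_jitter > 0:
        E = rng.normal(0.0, spec.subject_jitter, size=(p, p))
        E = (E + E.T) / 2.0
        np.fill_diagonal(E, 0.0)
        sigma = _nearest_correlation(target + E)
    else:
        sigma = target
    chol = np.linalg.cholesky(sigma)
    eps = rng.standard_normal((spec.T, p))
    if spec.ar1 > 0:
        # AR(1) innovations give temporally smooth series with the same
        # stationary correlation structure
        for t in range(1, spec.T):
            eps[t] = spec.ar1 * eps[t - 1] + np.sqrt(1 - spec.ar1**2) * eps[t]
    return eps @ chol.T


def sample_cohort(spec: CohortSpec) -> tuple[list[RoiTimeSeries], list[int]]:
    """Draw the full cohort; patients labelled 1, controls 0.

    Deterministic under ``spec.seed``.
    """
    targets = {
        "hc": build_group_correlation(spec, "hc"),
        "asd": build_group_correlation(spec, "asd"),
    }
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    series, labels = [], []
    for group, label in (("asd", 1), ("hc", 0)):
        for s in range(spec.n_per_group):
            data = _sample_subject(rng, targets[group], spec)
            series.append(RoiTimeSeries(f"{group}_{s:04d}", data))
            labels.append(label)
    return series, labels


def planted_truth(spec: CohortSpec, index_map: EdgeIndexMap | None = None) -> np.ndarray:
    """Flat feature indices of the planted edges."""
    imap = index_map or EdgeIndexMap(spec.p)
    return np.sort([imap.index(i, j) for (i, j) in spec.planted_edges]).astype(int)


def simulate_dataset(spec: CohortSpec) -> LabeledDataset:
    """Cohort sampled and pushed through the full feature-extraction path."""
    series, labels = sample_cohort(spec)
    return build_dataset(series, labels)
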