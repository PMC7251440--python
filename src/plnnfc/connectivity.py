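"""Resting-state functional-connectivity feature extraction.

Each subject contributes a (T timepoints x p ROIs) BOLD time-series matrix.
Edges are Pearson correlations between ROI time series; the p x p matrix is
Fisher z-transformed (arctanh, variance stabilizing) and its strict upper
triangle flattened into a length p(p-1)/2 feature vector.  The flattening
order is fixed and documented by :class:`EdgeIndexMap` so that feature
indices are reproducible across runs and exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "ConnectivityMatrix",
    "FeatureVector",
    "EdgeIndexMap",
    "LabeledDataset",
    "pearson_matrix",
    "fisher_z",
    "flatten_upper",
    "unflatten_upper",
    "build_dataset",
]

DEFAULT_CLIP = 1.0 - 1e-7


@dataclass
class RoiTimeSeries:
    """BOLD time series for one subject: ``data`` is T x p (rows = time)."""

    subject_id: str
    data: np.ndarray
    roi_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: time series must be 2-D (T x p)")
        T, p = self.data.shape
        if T < 3:
            raise ValueError(f"{self.subject_id}: need at least 3 timepoints, got {T}")
        if p < 2:
            raise ValueError(f"{self.subject_id}: need at least 2 ROIs, got {p}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: non-finite values in time series")

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric p x p edge matrix (Pearson r, or Fisher z after transform)."""

    subject_id: str
    r: np.ndarray
    is_fisher_z: bool = False

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("connectivity matrix must be square")

    @property
    def p(self) -> int:
        return self.r.shape[0]


@dataclass
class FeatureVector:
    """Flattened upper-triangle edge features for one subject."""

    subject_id: str
    z: np.ndarray
    p: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        d = self.p * (self.p - 1) // 2
        if self.z.size != d:
            raise ValueError(f"expected {d} features for p={self.p}, got {self.z.size}")


class EdgeIndexMap:
    """Bijection between flat feature index k and ordered ROI pair (i, j), i < j.

    Row-major strict upper triangle, 0-based: k enumerates
    (0,1), (0,2), ..., (0,p-1), (1,2), ..., (p-2,p-1).
    """

    def __init__(self, p: int):
        if p < 2:
            raise ValueError("p must be >= 2")
        self.p = int(p)
        self._rows, self._cols = np.triu_indices(self.p, k=1)

    @property
    def n_features(self) -> int:
        return self.p * (self.p - 1) // 2

    def pair(self, k: int) -> tuple[int, int]:
        if not 0 <= k < self.n_features:
            raise IndexError(f"feature index {k} out of range [0, {self.n_features})")
        return int(self._rows[k]), int(self._cols[k])

    def index(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("diagonal entries are not features")
        if i > j:
            i, j = j, i
        if not (0 <= i < j < self.p):
            raise ValueError(f"pair ({i},{j}) out of range for p={self.p}")
        # row-major offset: rows 0..i-1 contribute (p-1-row) entries each
        return i * (2 * self.p - i - 1) // 2 + (j - i - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(self.n_features), "roi_i": self._rows, "roi_j": self._cols}
        )


@dataclass
class LabeledDataset:
    """Stacked feature matrix X (n x d) with binary labels (positive group = 1)."""

    X: np.ndarray
    y: np.ndarray
    subject_ids: list[str]
    p: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int).ravel()
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.subject_ids):
            raise ValueError("X, y and subject_ids must agree in length")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between all ROI pairs of one subject.

    Raises if any ROI column is constant (correlation undefined).
    """
    data = ts.data
    sd = data.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (
            [ts.roi_labels[i] for i in bad] if ts.roi_labels is not None else bad.tolist()
        )
        raise ValueError(f"{ts.subject_id}: zero-variance ROI column(s): {names}")
    r = np.corrcoef(data, rowvar=False)
    # corrcoef can drift past +/-1 by float error; clamp and pin the diagonal
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return ConnectivityMatrix(ts.subject_id, r)


def fisher_z(c: ConnectivityMatrix, clip: float = DEFAULT_CLIP) -> ConnectivityMatrix:
    """Fisher z-transform (arctanh) of the off-diagonal entries.

    Correlations are clipped to [-clip, clip] first so that |r| = 1 maps to a
    finite value.  The diagonal is left untouched; it never enters features.
    """
    if not 0.0 < clip < 1.0:
        raise ValueError("clip must be in (0, 1)")
    r = c.r
    z = np.arctanh(np.clip(r, -clip, clip))
    np.fill_diagonal(z, np.diag(r))
    return ConnectivityMatrix(c.subject_id, z, is_fisher_z=True)


def flatten_upper(c: ConnectivityMatrix) -> FeatureVector:
    """Flatten the strict upper triangle in :class:`EdgeIndexMap` order."""
    m = c.r
    off_diag = m - np.diag(np.diag(m))
    if not np.allclose(off_diag, off_diag.T, atol=1e-10):
        raise ValueError(f"{c.subject_id}: matrix is not symmetric off the diagonal")
    iu = np.triu_indices(c.p, k=1)
    return FeatureVector(c.subject_id, m[iu], c.p)


def unflatten_upper(v: FeatureVector) -> np.ndarray:
    """Inverse of :func:`flatten_upper`; reconstructs the symmetric off-diagonal
    matrix with a zero diagonal."""
    m = np.zeros((v.p, v.p))
    iu = np.triu_indices(v.p, k=1)
    m[iu] = v.z
    return m + m.T


def build_dataset(
    series: Sequence[RoiTimeSeries],
    labels: Sequence[int],
    clip: float = DEFAULT_CLIP,
) -> LabeledDataset:
    """Full extraction: Pearson -> Fisher z -> flatten, stacked over subjects."""
    if len(series) == 0:
        raise ValueError("empty subject list")
    if len(series) != len(labels):
        raise ValueError("series and labels must have equal length")
    p = series[0].n_rois
    offenders = [ts.subject_id for ts in series if ts.n_rois != p]
    if offenders:
        raise ValueError(f"inconsistent ROI count; offending subjects: {offenders}")
    rows = [flatten_upper(fisher_z(pearson_matrix(ts), clip)).z for ts in series]
    return LabeledDataset(
        X=np.vstack(rows),
        y=np.asarray(labels, dtype=int),
        subject_ids=[ts.subject_id for ts in series],
        p=p,
    )
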