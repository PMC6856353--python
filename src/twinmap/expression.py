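"""K-means clustering of gene x region expression profiles with elbow-based
selection of the number of clusters.

Rows (genes) are z-scored across regions before clustering so that profile
shape, not expression level, drives the grouping.  The number of clusters is
chosen at the elbow of the within-cluster sum-of-squares (WSS) curve: the k
lying furthest below the chord joining the curve's endpoints (the "knee"
point of maximum curvature).  If no point dips at least ``min_depth`` of the
total sum of squares below the chord the curve is judged elbow-free and a
single cluster is returned — the WSS of structureless data declines smoothly
in k, so raw curvature alone would always nominate some k > 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans


@dataclass
class ExpressionMatrix:
    """A genes x regions expression matrix with unique labels."""

    values: np.ndarray
    gene_labels: list[str]
    region_labels: list[str]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (genes x regions)")
        if self.values.shape != (len(self.gene_labels), len(self.region_labels)):
            raise ValueError("labels do not match matrix shape")
        if len(set(self.gene_labels)) != len(self.gene_labels):
            raise ValueError("gene labels must be unique")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_labels,
                            columns=self.region_labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, normalized: bool = False):
        return cls(df.to_numpy(float), [str(g) for g in df.index],
                   [str(r) for r in df.columns], normalized)


def filter_genes(matrix: ExpressionMatrix, exclusion_list=(),
                 availability_mask=None) -> ExpressionMatrix:
    """Drop excluded genes (e.g. the MHC region, where long-range LD makes
    associations suspect) and genes without available measurements."""
    excl = set(exclusion_list)
    keep = np.ones(matrix.n_genes, dtype=bool)
    for i, g in enumerate(matrix.gene_labels):
        if g in excl:
            keep[i] = False
    if availability_mask is not None:
        keep &= np.asarray(availability_mask, dtype=bool)
    if not keep.any():
        raise ValueError("gene filtering removed every gene")
    return ExpressionMatrix(
        matrix.values[keep],
        [g for g, k in zip(matrix.gene_labels, keep) if k],
        list(matrix.region_labels), matrix.normalized,
    )


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    out = np.where(sd > 1e-12, (X - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return out


class ElbowKMeans(BaseEstimator, ClusterMixin):
    """K-means with the cluster count chosen by the elbow (max-curvature) rule.

    Parameters
    ----------
    k_range : iterable of int
        Candidate cluster counts (default 1..8, clipped to n_genes).
    n_init : int
        Restarts per k; the best (lowest WSS) solution is kept.
    standardize : bool
        Z-score rows across regions before clustering (default True).
    min_depth : float
        Minimum fraction of the total sum of squares by which the elbow must
        undercut the WSS chord; below it the curve is treated as elbow-free
        and one cluster is returned.
    random_state : int or None

    Attributes
    ----------
    labels_ : cluster assignment per row at the chosen k.
    chosen_k_ : selected number of clusters.
    wss_curve_ : dict k -> within-cluster sum of squares.
    """

    def __init__(self, k_range=range(1, 9), n_init=10, standardize=True,
                 min_depth=0.2, random_state=None):
        self.k_range = k_range
        self.n_init = n_init
        self.standardize = standardize
        self.min_depth = min_depth
        self.random_state = random_state

    def fit(self, X, y=None):
        if isinstance(X, ExpressionMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        ks = sorted(int(k) for k in self.k_range)
        if not ks or ks[0] < 1 or ks[-1] > X.shape[0]:
            raise ValueError("k_range must lie within [1, n_genes]")
        Z = _zscore_rows(X) if self.standardize else X
        wss: dict[int, float] = {}
        labels: dict[int, np.ndarray] = {}
        for k in ks:
            if k == 1:
                centroid = Z.mean(axis=0)
                wss[k] = float(((Z - centroid) ** 2).sum())
                labels[k] = np.zeros(Z.shape[0], dtype=int)
            else:
                km = KMeans(n_clusters=k, n_init=self.n_init,
                            random_state=self.random_state).fit(Z)
                wss[k] = float(km.inertia_)
                labels[k] = km.labels_
        self.wss_curve_ = wss
        total = float(((Z - Z.mean(0)) ** 2).sum())
        if total < 1e-10 or len(ks) < 3:
            # degenerate matrix (all profiles identical) or too few candidates
            self.chosen_k_ = ks[0]
        else:
            karr = np.asarray(ks, dtype=float)
            curve = np.array([wss[k] for k in ks])
            chord = curve[0] + (curve[-1] - curve[0]) * (karr - karr[0]) \
                / (karr[-1] - karr[0])
            depth = (chord - curve) / total
            if depth.max() < self.min_depth:
                self.chosen_k_ = ks[0]
            else:
                self.chosen_k_ = ks[int(np.argmax(depth))]
        self.labels_ = labels[self.chosen_k_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans_elbow(matrix, k_range=range(1, 9), n_init: int = 10, seed=None):
    """Functional wrapper: returns ``(labels, chosen_k, wss_curve)``."""
    est = ElbowKMeans(k_range=k_range, n_init=n_init, random_state=seed).fit(matrix)
    return est.labels_, est.chosen_k_, est.wss_curve_
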