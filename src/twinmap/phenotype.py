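"""Behavioral-scale scoring, transformation and covariate residualization.

Scale scores follow the prorated-total convention: the mean of the answered
items (reverse-coded where flagged) multiplied by the number of items,
provided at least a minimum fraction (default 80%) of items were answered.
Scores are square-root transformed to improve normality, and every variable
entering a twin model is residualized on covariates (sex, mean cortical
thickness) by OLS beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ScaleDefinition:
    """A Likert scale: item count, reverse-coded items, completion rule."""

    name: str
    n_items: int
    reverse_coded: frozenset[int] = field(default_factory=frozenset)
    min_completion: float = 0.8
    likert_min: int = 0
    likert_max: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.min_completion <= 1.0:
            raise ValueError("min_completion must be in (0, 1]")
        self.reverse_coded = frozenset(self.reverse_coded)
        if any(i < 0 or i >= self.n_items for i in self.reverse_coded):
            raise ValueError("reverse-coded item index out of range")


def score_scale(responses, definition: ScaleDefinition) -> float:
    """Prorated scale total, or NaN if completion falls below the threshold.

    Reverse-coded items are mapped to ``likert_max + likert_min - response``
    before averaging; the mean of the observed items is multiplied by the
    total item count.
    """
    r = np.asarray(responses, dtype=float)
    if r.shape != (definition.n_items,):
        raise ValueError(
            f"expected {definition.n_items} responses, got {r.shape}"
        )
    obs = np.isfinite(r)
    vals = r[obs]
    if ((vals < definition.likert_min) | (vals > definition.likert_max)).any():
        raise ValueError("response outside the Likert range")
    if obs.sum() / definition.n_items < definition.min_completion - 1e-12:
        return float("nan")
    rev = np.array([i in definition.reverse_coded for i in range(definition.n_items)])
    flipped = np.where(rev, definition.likert_max + definition.likert_min - r, r)
    return float(np.nanmean(flipped) * definition.n_items)


def sqrt_transform(score) -> np.ndarray | float:
    """Square-root transform of a nonnegative score (NaN passes through)."""
    s = np.asarray(score, dtype=float)
    if np.any(s[np.isfinite(s)] < 0):
        raise ValueError("square-root transform requires nonnegative scores")
    out = np.sqrt(s)
    return float(out) if out.ndim == 0 else out


def _design(covariates, n: int) -> np.ndarray:
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValueError("covariate rows must match observations")
    return np.column_stack([np.ones(n), C])


def residualize(y, covariates) -> np.ndarray:
    """OLS residual of ``y`` on an intercept plus covariates.

    Rows with missing ``y`` stay missing; missing covariates on observed rows
    are rejected, as is a rank-deficient design.
    """
    y = np.asarray(y, dtype=float)
    X = _design(covariates, y.shape[0])
    obs = np.isfinite(y)
    if not np.isfinite(X[obs]).all():
        raise ValueError("missing covariates for rows with observed outcome")
    Xo = X[obs]
    # mutually collinear covariates are rejected; a covariate collinear with
    # the intercept alone (constant column) just reduces to demeaning
    if np.linalg.matrix_rank(Xo[:, 1:]) < Xo.shape[1] - 1:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(Xo, y[obs], rcond=None)
    out = np.full_like(y, np.nan)
    out[obs] = y[obs] - Xo @ beta
    return out


def partial_correlation(x, y, covariates) -> float:
    """Pearson correlation of two OLS-residualized vectors.

    Returns NaN when either residual vector is (numerically) constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    if ok.sum() < 3 + C.shape[1]:
        raise ValueError("insufficient complete rows for a partial correlation")
    rx = residualize(x[ok], C[ok])
    ry = residualize(y[ok], C[ok])
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 * max(1.0, abs(x[ok]).max()) or \
       sy < 1e-12 * max(1.0, abs(y[ok]).max()):
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])
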