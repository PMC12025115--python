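"""Compositional descriptive statistics in Aitchison geometry.

Centers (closed geometric means), the variation matrix (variances of
pairwise log ratios), total metric variance, and (weighted) log-ratio
distances between samples.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import CompositionTable, CompositionError, close_vector
from .transforms import PartWeights, clr, weighted_logratio_coords, _check_positive

__all__ = [
    "center",
    "variation_matrix",
    "total_variance",
    "aitchison_distance",
    "DistanceMatrix",
    "pairwise_distances",
]


def center(table: CompositionTable, kappa: float = 100.0) -> np.ndarray:
    """Compositional center: closed vector of column-wise geometric means.

    Satisfies the center-ratio identity
    ``center_i / center_j = exp(mean_n ln(x_i / x_j))`` for every pair,
    i.e. center component ratios are geometric-mean sample ratios.
    """
    _check_positive(table.values, table)
    gm = np.exp(np.log(table.values).mean(axis=0))
    return close_vector(gm, kappa)


def variation_matrix(table: CompositionTable, ddof: int = 1) -> pd.DataFrame:
    """Variation matrix T with T[i, j] = var_n ln(x_i / x_j).

    Symmetric with zero diagonal; near-zero entries flag proportional
    (co-varying) parts. ``ddof=1`` gives the sample (n-1) variance.
    """
    if table.n_samples < 2:
        raise CompositionError("variation matrix needs at least 2 samples")
    _check_positive(table.values, table)
    lm = np.log(table.values)
    D = table.n_parts
    T = np.zeros((D, D))
    for i in range(D):
        for j in range(i + 1, D):
            v = np.var(lm[:, i] - lm[:, j], ddof=ddof)
            T[i, j] = T[j, i] = v
    return pd.DataFrame(T, index=table.part_names, columns=table.part_names)


def total_variance(
    table: CompositionTable,
    weights: PartWeights | None = None,
    ddof: int = 1,
) -> float:
    """Total (metric) variance: a single-number spread measure.

    Unweighted: the sum over parts of the variances of the CLR
    coordinates, which equals ``(1/(2D)) * sum(variation_matrix)``.
    Weighted: ``sum_j w_j var(wclr_j)`` with the weighted CLR
    ``ln x_j - sum_k w_k ln x_k``.
    """
    if table.n_samples < 2:
        raise CompositionError("total variance needs at least 2 samples")
    if weights is None:
        y = clr(table)
        return float(np.var(y, axis=0, ddof=ddof).sum())
    if tuple(table.part_names) != weights.parts:
        raise CompositionError("weight parts do not match table parts")
    y = weighted_logratio_coords(table, weights)  # already sqrt(w)-scaled
    return float(np.var(y, axis=0, ddof=ddof).sum())


def aitchison_distance(
    x: np.ndarray | Sequence[float],
    y: np.ndarray | Sequence[float],
    weights: PartWeights | None = None,
) -> float:
    """(Weighted) log-ratio distance between two compositions.

    Unweighted: Euclidean norm of ``clr(x) - clr(y)`` (classic Aitchison
    distance). Weighted: ``sqrt(sum_j w_j (lx_j - ly_j)^2)`` on the
    weighted CLR coordinates. Scale-invariant and perturbation-invariant
    in both cases.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CompositionError("compositions must have the same parts")
    if weights is None:
        return float(np.linalg.norm(clr(x) - clr(y)))
    if len(weights.parts) != x.shape[0]:
        raise CompositionError("weight parts do not match composition length")
    return float(
        np.linalg.norm(
            weighted_logratio_coords(x, weights) - weighted_logratio_coords(y, weights)
        )
    )


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with sample ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise CompositionError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise CompositionError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise CompositionError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise CompositionError("distances must be non-negative")
        self.d = (self.d + self.d.T) / 2
        np.fill_diagonal(self.d, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangular condensed form (scipy convention)."""
        from scipy.spatial.distance import squareform

        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def pairwise_distances(
    table: CompositionTable, weights: PartWeights | None = None
) -> DistanceMatrix:
    """All pairwise (weighted) log-ratio distances between samples."""
    if weights is None:
        y = clr(table)
    else:
        y = weighted_logratio_coords(table, weights)
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(y, metric="euclidean"))
    return DistanceMatrix(list(table.sample_ids), d)
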