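"""Log-ratio transforms and bases for Aitchison geometry.

The centred log-ratio (CLR) maps a D-part composition onto the zero-sum
hyperplane of R^D; an isometric log-ratio (ILR) basis built from a
sequential binary partition (SBP) gives orthonormal coordinates in which
Euclidean distance equals Aitchison distance. A weighted variant
(weights w_j > 0, sum 1) supports the weighted log-ratio metric used for
clustering, in which the geometric mean in the CLR is weight-averaged
and coordinates are scaled by sqrt(w_j).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .composition import CompositionTable, CompositionError, close_vector

__all__ = [
    "ContrastMatrix",
    "PartWeights",
    "make_sbp_basis",
    "clr",
    "clr_inv",
    "ilr",
    "ilr_inv",
    "pairwise_logratios",
    "weighted_logratio_coords",
    "CLRTransformer",
    "ILRTransformer",
]


def _as_matrix(x: CompositionTable | np.ndarray) -> np.ndarray:
    if isinstance(x, CompositionTable):
        m = x.values
    else:
        m = np.asarray(x, dtype=float)
    single = m.ndim == 1
    m = np.atleast_2d(m)
    return m, single


def _check_positive(m: np.ndarray, table: CompositionTable | None = None) -> None:
    bad = np.argwhere(m <= 0)
    if bad.size:
        i, j = bad[0]
        if table is not None:
            raise CompositionError(
                f"non-positive value for part {table.part_names[j]!r} in "
                f"sample {table.sample_ids[i]!r}; replace zeros first"
            )
        raise CompositionError("compositions must be strictly positive")


@dataclasses.dataclass(frozen=True)
class ContrastMatrix:
    """Orthonormal ILR balance basis for an ordered list of parts.

    ``basis`` is (D-1) x D; rows are orthonormal and each sums to zero
    (they live in the CLR plane). ``partition`` records the sequential
    binary partition as sign vectors (+1 numerator, -1 denominator, 0
    not involved) so reports can print which balances were used.
    """

    parts: tuple[str, ...]
    basis: np.ndarray
    partition: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        D = len(self.parts)
        b = np.asarray(self.basis, dtype=float)
        if b.shape != (D - 1, D):
            raise CompositionError(f"basis must be {(D - 1, D)}, got {b.shape}")
        if not np.allclose(b @ b.T, np.eye(D - 1), atol=1e-10):
            raise CompositionError("basis rows are not orthonormal")
        if not np.allclose(b.sum(axis=1), 0, atol=1e-10):
            raise CompositionError("basis rows must sum to zero")
        object.__setattr__(self, "basis", b)

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def describe(self) -> list[str]:
        """Human-readable balance definitions, one per coordinate."""
        out = []
        for signs in self.partition:
            num = [p for p, s in zip(self.parts, signs) if s > 0]
            den = [p for p, s in zip(self.parts, signs) if s < 0]
            out.append(f"[{' '.join(num)} | {' '.join(den)}]")
        return out


@dataclasses.dataclass(frozen=True)
class PartWeights:
    """Positive part weights summing to one (weighted Aitchison metric)."""

    parts: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (len(self.parts),):
            raise CompositionError("one weight per part required")
        if np.any(w <= 0):
            raise CompositionError("weights must be strictly positive")
        object.__setattr__(self, "w", w / w.sum())

    @classmethod
    def uniform(cls, parts: Sequence[str]) -> "PartWeights":
        D = len(parts)
        return cls(tuple(parts), np.full(D, 1.0 / D))

    @classmethod
    def from_table(cls, table: CompositionTable) -> "PartWeights":
        """Column-mean proportions of the closed table (the default of the
        weighted log-ratio toolchain convention)."""
        props = table.values / table.values.sum(axis=1, keepdims=True)
        return cls(tuple(table.part_names), props.mean(axis=0))


def make_sbp_basis(
    parts: Sequence[str],
    partition: Sequence[Sequence[int]] | None = None,
) -> ContrastMatrix:
    """Build an orthonormal balance basis from a sequential binary partition.

    ``partition`` is a list of D-1 sign vectors over the parts (+1 / -1 /
    0). The default is the pivot sequence: part 1 against the rest, part
    2 against the remaining rest, and so on. Each balance row is

        b = sqrt(r*s/(r+s)) * (mean over numerator of e_i/r - ...),

    i.e. coefficient +sqrt(s/(r(r+s))) on each of the r numerator parts
    and -sqrt(r/(s(r+s))) on each of the s denominator parts.
    """
    parts = tuple(str(p) for p in parts)
    D = len(parts)
    if D < 2:
        raise CompositionError("need at least two parts")
    if partition is None:
        partition = []
        for k in range(D - 1):
            signs = [0] * D
            signs[k] = 1
            for j in range(k + 1, D):
                signs[j] = -1
            partition.append(signs)
    partition = [tuple(int(s) for s in row) for row in partition]
    if len(partition) != D - 1:
        raise CompositionError(
            f"partition must have {D - 1} rows, got {len(partition)}"
        )
    rows = []
    for signs in partition:
        if len(signs) != D or any(s not in (-1, 0, 1) for s in signs):
            raise CompositionError("partition rows must be +1/-1/0 over the parts")
        signs_arr = np.asarray(signs)
        r = int((signs_arr == 1).sum())
        s = int((signs_arr == -1).sum())
        if r == 0 or s == 0:
            raise CompositionError("each balance needs parts on both sides")
        row = np.zeros(D)
        row[signs_arr == 1] = np.sqrt(s / (r * (r + s)))
        row[signs_arr == -1] = -np.sqrt(r / (s * (r + s)))
        rows.append(row)
    basis = np.vstack(rows)
    try:
        return ContrastMatrix(parts, basis, tuple(partition))
    except CompositionError as e:
        raise CompositionError(f"partition does not define an SBP: {e}") from e


def clr(x: CompositionTable | np.ndarray) -> np.ndarray:
    """Centred log-ratio: ln(x_ij / g_i), g_i the row geometric mean.

    Rows sum to zero; scale-invariant per row.
    """
    m, single = _as_matrix(x)
    _check_positive(m, x if isinstance(x, CompositionTable) else None)
    lm = np.log(m)
    out = lm - lm.mean(axis=1, keepdims=True)
    return out[0] if single else out


def clr_inv(y: np.ndarray, kappa: float = 100.0) -> np.ndarray:
    """Map CLR coordinates back to closed compositions."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    y = np.atleast_2d(y)
    x = np.exp(y - y.max(axis=1, keepdims=True))
    x = kappa * x / x.sum(axis=1, keepdims=True)
    return x[0] if single else x


def ilr(
    x: CompositionTable | np.ndarray, basis: ContrastMatrix
) -> np.ndarray:
    """Isometric log-ratio coordinates: clr(x) @ basis.T."""
    if isinstance(x, CompositionTable):
        if tuple(x.part_names) != basis.parts:
            raise CompositionError(
                f"table parts {tuple(x.part_names)} do not match basis parts "
                f"{basis.parts}"
            )
    return clr(x) @ basis.basis.T


def ilr_inv(z: np.ndarray, basis: ContrastMatrix, kappa: float = 100.0) -> np.ndarray:
    """Map ILR coordinates back to closed compositions."""
    z = np.asarray(z, dtype=float)
    return clr_inv(z @ basis.basis, kappa=kappa)


def pairwise_logratios(
    table: CompositionTable, pairs: Sequence[tuple[str, str]] | None = None
) -> "pd.DataFrame":
    """All ordered pairwise log ratios ln(x_i / x_j) per sample.

    Antisymmetric in the pair order; by subcompositional coherence a
    ratio is unaffected by amalgamating or dropping *other* parts.
    """
    import pandas as pd

    _check_positive(table.values, table)
    if pairs is None:
        pairs = [
            (a, b)
            for a in table.part_names
            for b in table.part_names
            if a != b
        ]
    lm = np.log(table.values)
    cols = {}
    for a, b in pairs:
        ia, ib = table.part_index(a), table.part_index(b)
        cols[f"{a}/{b}"] = lm[:, ia] - lm[:, ib]
    return pd.DataFrame(cols, index=pd.Index(table.sample_ids, name="sample_id"))


def weighted_logratio_coords(
    x: CompositionTable | np.ndarray, weights: PartWeights
) -> np.ndarray:
    """Coordinates whose Euclidean distance is the weighted log-ratio metric.

    The weighted CLR of part j is ln x_j - sum_k w_k ln x_k; scaling each
    coordinate by sqrt(w_j) makes the plain Euclidean distance equal to
    sqrt(sum_j w_j (lx_j - ly_j)^2). With uniform weights this reduces to
    clr / sqrt(D), preserving classic Aitchison distances up to the
    constant factor absorbed in the definition below.
    """
    if isinstance(x, CompositionTable) and tuple(x.part_names) != weights.parts:
        raise CompositionError("weight parts do not match table parts")
    m, single = _as_matrix(x)
    _check_positive(m, x if isinstance(x, CompositionTable) else None)
    lm = np.log(m)
    wclr = lm - (lm @ weights.w)[:, None]
    out = wclr * np.sqrt(weights.w)[None, :]
    return out[0] if single else out


class CLRTransformer(TransformerMixin, BaseEstimator):
    """Centred log-ratio transform as a scikit-learn transformer.

    Stateless apart from recording the number of parts; provided so the
    transform composes with sklearn pipelines and model selection.
    """

    def fit(self, X, y=None):
        m, _ = _as_matrix(X)
        _check_positive(m)
        self.n_features_in_ = m.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        m, _ = _as_matrix(X)
        if m.shape[1] != self.n_features_in_:
            raise CompositionError(
                f"expected {self.n_features_in_} parts, got {m.shape[1]}"
            )
        return clr(m)

    def inverse_transform(self, X):
        return clr_inv(X, kappa=1.0)


class ILRTransformer(TransformerMixin, BaseEstimator):
    """ILR transform with a pivot or user-supplied SBP basis.

    Parameters
    ----------
    partition : list of sign vectors or None
        Sequential binary partition; None selects the pivot sequence in
        the input part order.
    """

    def __init__(self, partition=None):
        self.partition = partition

    def fit(self, X, y=None):
        m, _ = _as_matrix(X)
        _check_positive(m)
        parts = (
            tuple(X.part_names)
            if isinstance(X, CompositionTable)
            else tuple(f"p{j}" for j in range(m.shape[1]))
        )
        self.basis_ = make_sbp_basis(parts, self.partition)
        self.n_features_in_ = m.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        m, _ = _as_matrix(X)
        return clr(m) @ self.basis_.basis.T

    def inverse_transform(self, X):
        check_is_fitted(self)
        return ilr_inv(np.asarray(X, float), self.basis_, kappa=1.0)
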