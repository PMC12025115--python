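"""Composition tables: validated samples-by-parts percentage matrices.

A composition carries only relative information; the canonical internal
scale is percent (closure constant ``kappa = 100``), matching how EDX
quantification reports element proportions. Closure is always an explicit
step: tables read from disk keep their raw row sums until :func:`close`
is called.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionTable",
    "CompositionError",
    "read_composition_csv",
    "write_composition_csv",
    "close",
    "amalgamate",
    "replace_zeros",
    "DEFAULT_PARTS",
    "TRACE_PARTS",
]

#: Element columns of the standard input schema, in acquisition order.
DEFAULT_PARTS = ("C", "O", "Ca", "Mg", "Cl", "F", "P")

#: Low-abundance elements amalgamated into the single part "Traces".
TRACE_PARTS = ("Cl", "F", "P")


class CompositionError(ValueError):
    """Raised for malformed or invalid composition data."""


@dataclasses.dataclass
class CompositionTable:
    """Samples x parts matrix of non-negative percentages plus metadata.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers (one per row).
    part_names : sequence of str
        Unique part (element) names, one per column.
    values : ndarray of shape (n_samples, n_parts)
        Non-negative part values; rows need not be closed.
    meta : pandas.DataFrame, optional
        Per-sample metadata (e.g. ``specimen``, ``prep``, ``label``),
        indexed like ``sample_ids``.
    """

    sample_ids: list[str]
    part_names: list[str]
    values: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.part_names = [str(p) for p in self.part_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CompositionError("values must be a 2-D array")
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise CompositionError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if d != len(self.part_names):
            raise CompositionError(
                f"{len(self.part_names)} part names for {d} columns"
            )
        if len(set(self.sample_ids)) != n:
            dupes = _duplicates(self.sample_ids)
            raise CompositionError(f"duplicate sample ids: {dupes}")
        if len(set(self.part_names)) != d:
            dupes = _duplicates(self.part_names)
            raise CompositionError(f"duplicate part names: {dupes}")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise CompositionError(
                f"negative value for part {self.part_names[j]!r} in sample "
                f"{self.sample_ids[i]!r}"
            )
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            raise CompositionError(
                f"sample {self.sample_ids[zero_rows[0]]!r} is entirely zero"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            self.meta = self.meta.copy()
            self.meta.index = pd.Index(self.sample_ids, name="sample_id")

    # -- basic container protocol -------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_parts(self) -> int:
        return self.values.shape[1]

    def part_index(self, part: str) -> int:
        try:
            return self.part_names.index(part)
        except ValueError:
            raise CompositionError(f"unknown part {part!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.part_names,
        )

    def select_parts(self, parts: Sequence[str]) -> "CompositionTable":
        """Subcomposition / reordering by part name (no closure applied)."""
        idx = [self.part_index(p) for p in parts]
        return CompositionTable(
            self.sample_ids, list(parts), self.values[:, idx], self.meta
        )

    def select_samples(self, mask: np.ndarray | Sequence[bool]) -> "CompositionTable":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(np.arange(self.n_samples), mask)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return CompositionTable(
            ids, self.part_names, self.values[mask], self.meta.loc[ids]
        )

    def copy(self) -> "CompositionTable":
        return CompositionTable(
            list(self.sample_ids), list(self.part_names), self.values.copy(), self.meta
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


def read_composition_csv(
    path: str | Path,
    part_columns: Sequence[str] = DEFAULT_PARTS,
    sample_id_column: str = "sample_id",
) -> CompositionTable:
    """Read a composition table from CSV.

    Expected schema: a ``sample_id`` column, the named part columns, and
    any number of extra columns which are preserved as metadata
    (``specimen``, ``prep``, ``cluster`` ...). Rows are NOT closed on
    read; call :func:`close` explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in (sample_id_column, *part_columns) if c not in df.columns]
    if missing:
        raise CompositionError(
            f"{path.name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    sample_ids = df[sample_id_column].astype(str).tolist()
    vals = df[list(part_columns)].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(vals.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise CompositionError(
            f"{path.name}: non-numeric value for part {part_columns[j]!r} "
            f"in sample {sample_ids[i]!r}"
        )
    meta_cols = [c for c in df.columns if c not in part_columns and c != sample_id_column]
    meta = df[meta_cols].copy() if meta_cols else None
    return CompositionTable(sample_ids, list(part_columns), vals.to_numpy(float), meta)


def write_composition_csv(table: CompositionTable, path: str | Path) -> None:
    """Write a table (values + metadata columns) to CSV, full precision."""
    df = table.to_frame()
    out = pd.concat([df, table.meta], axis=1)
    out.to_csv(path, index=True, float_format="%.17g")


def close(table: CompositionTable, kappa: float = 100.0) -> CompositionTable:
    """Rescale every row to sum to the closure constant ``kappa``.

    Within-row ratios are unchanged; idempotent.
    """
    if kappa <= 0:
        raise CompositionError("kappa must be positive")
    sums = table.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        raise CompositionError(
            f"sample {table.sample_ids[bad[0]]!r} has non-positive row sum"
        )
    vals = table.values * (kappa / sums)[:, None]
    return CompositionTable(table.sample_ids, table.part_names, vals, table.meta)


def close_vector(x: np.ndarray | Sequence[float], kappa: float = 100.0) -> np.ndarray:
    """Closure of a single composition vector."""
    x = np.asarray(x, dtype=float)
    s = x.sum()
    if s <= 0:
        raise CompositionError("vector has non-positive sum")
    return x * (kappa / s)


def amalgamate(
    table: CompositionTable,
    parts: Sequence[str] | set[str],
    new_name: str = "Traces",
) -> CompositionTable:
    """Replace the named parts with a single part equal to their row sum.

    Amalgamation is performed on the raw (percent) scale, before any
    log-ratio transform; row sums are unchanged. The new part takes the
    column position of the first amalgamated part.
    """
    parts = list(parts)
    if not parts:
        raise CompositionError("no parts to amalgamate")
    if new_name in set(table.part_names) - set(parts):
        raise CompositionError(f"part name {new_name!r} already present")
    idx = [table.part_index(p) for p in parts]
    keep = [j for j in range(table.n_parts) if j not in idx]
    insert_at = min(idx)
    new_names: list[str] = []
    cols: list[np.ndarray] = []
    placed = False
    for j in range(table.n_parts):
        if j in idx:
            if not placed and j == insert_at:
                new_names.append(new_name)
                cols.append(table.values[:, idx].sum(axis=1))
                placed = True
            continue
        new_names.append(table.part_names[j])
        cols.append(table.values[:, j])
    return CompositionTable(
        table.sample_ids, new_names, np.column_stack(cols), table.meta
    )


def replace_zeros(
    table: CompositionTable, delta: float = 0.005
) -> tuple[CompositionTable, int]:
    """Multiplicative replacement of exact zeros.

    Every zero becomes ``delta`` (on the row's own scale: delta is in the
    units of the row sum, i.e. percent for closed tables) and the
    remaining parts of that row are shrunk proportionally so the row sum
    is preserved. Returns the new table and the number of replaced cells.

    The default ``delta = 0.005`` percent is half the smallest resolution
    at which the element tables are printed (0.01%), so replacement never
    distorts a printed value.
    """
    if delta <= 0:
        raise CompositionError("delta must be positive")
    vals = table.values.copy()
    n_replaced = int((vals == 0).sum())
    if n_replaced:
        for i in range(vals.shape[0]):
            row = vals[i]
            zero = row == 0
            if not zero.any():
                continue
            total = row.sum()
            fill = delta * zero.sum()
            if fill >= total:
                raise CompositionError(
                    f"delta too large for sample {table.sample_ids[i]!r}"
                )
            row[~zero] *= (total - fill) / total
            row[zero] = delta
    return (
        CompositionTable(table.sample_ids, table.part_names, vals, table.meta),
        n_replaced,
    )
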