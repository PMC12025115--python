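"""Cluster characterization: centers, spread, ratio tables and plot
coordinates.

These outputs mirror the standard descriptive toolkit of compositional
data analysis: per-cluster centers and total variance, variation
matrices, min - geometric mean - max pairwise ratio tables, centred
ternary coordinates against the geometric mean of the remaining parts,
and log-ratio (form) biplot coordinates from the SVD of the
double-centred log matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import CompositionTable, CompositionError, close_vector
from .stats import center, total_variance, variation_matrix
from .transforms import PartWeights, _check_positive

__all__ = [
    "ClusterSummary",
    "summarize_cluster",
    "summarize_all",
    "ratio_summary",
    "ternary_coordinates",
    "logratio_boxstats",
    "logratio_biplot_coords",
]


@dataclasses.dataclass
class ClusterSummary:
    """Center, spread and ratio table of one cluster.

    ``ratio_table`` holds, for every ordered part pair (row, column),
    the minimum, geometric mean and maximum of the per-sample ratios;
    the geometric mean equals the ratio of the corresponding center
    components exactly, and the (j, i) cell is the reciprocal of (i, j)
    with min and max swapped.
    """

    name: str
    n: int
    center: pd.Series  # percent, sums to 100
    total_variance: float
    variation: pd.DataFrame
    ratio_table: pd.DataFrame  # MultiIndex (pair) -> min, mean, max

    def ratio_cell(self, num: str, den: str, decimals: int | None = 2) -> tuple:
        row = self.ratio_table.loc[(num, den)]
        vals = (row["min"], row["mean"], row["max"])
        if decimals is None:
            return vals
        return tuple(round(v, decimals) for v in vals)


def _ratio_table(table: CompositionTable) -> pd.DataFrame:
    _check_positive(table.values, table)
    lm = np.log(table.values)
    rows = []
    for i, a in enumerate(table.part_names):
        for j, b in enumerate(table.part_names):
            if i == j:
                continue
            lr = lm[:, i] - lm[:, j]
            rows.append(
                {
                    "num": a,
                    "den": b,
                    "min": float(np.exp(lr.min())),
                    "mean": float(np.exp(lr.mean())),
                    "max": float(np.exp(lr.max())),
                }
            )
    return pd.DataFrame(rows).set_index(["num", "den"])


def summarize_cluster(
    table: CompositionTable,
    labels: Sequence[str] | pd.Series,
    name: str,
    weights: PartWeights | None = None,
    ddof: int = 1,
) -> ClusterSummary:
    """Assemble the full descriptive summary of one labelled cluster."""
    if isinstance(labels, pd.Series):
        labels = labels.reindex(table.sample_ids).to_numpy()
    labels = np.asarray([str(l) for l in labels])
    mask = labels == str(name)
    if not mask.any():
        raise CompositionError(f"cluster {name!r} is empty")
    sub = table.select_samples(mask)
    c = pd.Series(center(sub), index=sub.part_names, name=name)
    tv = total_variance(sub, weights=weights, ddof=ddof) if sub.n_samples > 1 else 0.0
    vm = (
        variation_matrix(sub, ddof=ddof)
        if sub.n_samples > 1
        else pd.DataFrame(
            np.zeros((sub.n_parts, sub.n_parts)),
            index=sub.part_names,
            columns=sub.part_names,
        )
    )
    return ClusterSummary(
        name=str(name),
        n=int(mask.sum()),
        center=c,
        total_variance=tv,
        variation=vm,
        ratio_table=_ratio_table(sub),
    )


def summarize_all(
    table: CompositionTable,
    labels: Sequence[str] | pd.Series,
    weights: PartWeights | None = None,
    ddof: int = 1,
) -> dict[str, ClusterSummary]:
    if isinstance(labels, pd.Series):
        labels = labels.reindex(table.sample_ids).to_numpy()
    labels = np.asarray([str(l) for l in labels])
    return {
        g: summarize_cluster(table, labels, g, weights=weights, ddof=ddof)
        for g in sorted(set(labels))
    }


def ratio_summary(
    table: CompositionTable,
    labels: Sequence[str] | pd.Series,
    decimals: int = 2,
) -> pd.DataFrame:
    """Formatted "min - mean - max" ratio table across all clusters.

    The mean is the geometric mean of the per-sample ratios (equal to
    exp of the mean log ratio and to the center-component ratio).
    Rounding to ``decimals`` is display-only; use
    :class:`ClusterSummary` for full precision.
    """
    summaries = summarize_all(table, labels)
    rows = []
    for g, s in summaries.items():
        for (num, den), r in s.ratio_table.iterrows():
            rows.append(
                {
                    "cluster": g,
                    "ratio": f"{num}/{den}",
                    "display": (
                        f"{round(r['min'], decimals)}-"
                        f"{round(r['mean'], decimals)}-"
                        f"{round(r['max'], decimals)}"
                    ),
                    "min": r["min"],
                    "mean": r["mean"],
                    "max": r["max"],
                }
            )
    return pd.DataFrame(rows)


def ternary_coordinates(
    table: CompositionTable,
    pair: tuple[str, str],
    centered: bool = True,
) -> pd.DataFrame:
    """Two-part ternary coordinates against the remaining parts' mean.

    Builds the 3-part pseudo-composition (a, b, g) with g the geometric
    mean of all parts other than the pair, closes it, optionally centres
    the data by perturbing with the inverse of its own compositional
    center (so the center maps to the barycentre), and projects to the
    plane with vertices a=(0,0), b=(1,0), g=(1/2, sqrt(3)/2):

        x = (2b + g) / (2 (a+b+g)),   y = sqrt(3) g / (2 (a+b+g)).
    """
    a_name, b_name = pair
    if a_name == b_name:
        raise CompositionError("ternary pair must be two distinct parts")
    if table.n_parts < 3:
        raise CompositionError("ternary coordinates need at least 3 parts")
    _check_positive(table.values, table)
    ia, ib = table.part_index(a_name), table.part_index(b_name)
    rest = [j for j in range(table.n_parts) if j not in (ia, ib)]
    a = table.values[:, ia]
    b = table.values[:, ib]
    g = np.exp(np.log(table.values[:, rest]).mean(axis=1))
    comp = np.column_stack([a, b, g])
    comp = comp / comp.sum(axis=1, keepdims=True)
    if centered:
        ctr = np.exp(np.log(comp).mean(axis=0))
        comp = comp / ctr
        comp = comp / comp.sum(axis=1, keepdims=True)
    tot = comp.sum(axis=1)
    x = (2 * comp[:, 1] + comp[:, 2]) / (2 * tot)
    y = np.sqrt(3) / 2 * comp[:, 2] / tot
    out = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "a": comp[:, 0],
            "b": comp[:, 1],
            "g": comp[:, 2],
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    out.attrs["vertices"] = (a_name, b_name, "gmean(rest)")
    return out


def logratio_boxstats(
    table: CompositionTable,
    labels: Sequence[str] | pd.Series,
) -> pd.DataFrame:
    """Five-number boxplot summaries of pairwise log ratios per cluster.

    Quartiles use linear interpolation (type-7); whiskers extend to the
    most extreme observation within 1.5 IQR of the box; points beyond
    are listed as outliers.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(table.sample_ids).to_numpy()
    labels = np.asarray([str(l) for l in labels])
    _check_positive(table.values, table)
    lm = np.log(table.values)
    rows = []
    for g in sorted(set(labels)):
        mask = labels == g
        for i, a in enumerate(table.part_names):
            for j, b in enumerate(table.part_names):
                if i >= j:
                    continue
                lr = lm[mask, i] - lm[mask, j]
                q1, med, q3 = np.quantile(lr, [0.25, 0.5, 0.75])
                iqr = q3 - q1
                lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
                inside = lr[(lr >= lo_fence) & (lr <= hi_fence)]
                outliers = lr[(lr < lo_fence) | (lr > hi_fence)]
                rows.append(
                    {
                        "cluster": g,
                        "ratio": f"{a}/{b}",
                        "whisker_lo": float(inside.min()),
                        "q1": float(q1),
                        "median": float(med),
                        "q3": float(q3),
                        "whisker_hi": float(inside.max()),
                        "n_outliers": int(outliers.size),
                        "outliers": outliers.tolist(),
                    }
                )
    return pd.DataFrame(rows)


def logratio_biplot_coords(
    table: CompositionTable,
    weights: PartWeights | None = None,
) -> dict:
    """Scores and loadings of the first two log-ratio principal axes.

    SVD of the (optionally weighted) double-centred log matrix; the sum
    of squared singular values equals the total variance in the
    matching (ddof=0) convention, so explained-variance proportions are
    exact. Axis signs are fixed by making the largest-magnitude loading
    of each axis positive, so the output is deterministic.
    """
    if table.n_samples < 3 or table.n_parts < 3:
        raise CompositionError("biplot needs at least 3 samples and 3 parts")
    _check_positive(table.values, table)
    lm = np.log(table.values)
    n = table.n_samples
    if weights is None:
        colc = lm - lm.mean(axis=1, keepdims=True)  # clr
        X = colc - colc.mean(axis=0, keepdims=True)
        X = X / np.sqrt(n)
        col_scale = np.ones(table.n_parts)
    else:
        if tuple(table.part_names) != weights.parts:
            raise CompositionError("weight parts do not match table parts")
        colc = lm - (lm @ weights.w)[:, None]
        X = colc - colc.mean(axis=0, keepdims=True)
        col_scale = np.sqrt(weights.w)
        X = X * col_scale[None, :] / np.sqrt(n)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0:
        raise CompositionError("zero-variance data: biplot undefined")
    for ax in range(len(s)):
        j = int(np.argmax(np.abs(Vt[ax])))
        if Vt[ax, j] < 0:
            Vt[ax] *= -1
            U[:, ax] *= -1
    k = min(2, len(s))
    scores = np.sqrt(n) * U[:, :k] * s[:k]
    return {
        "scores": pd.DataFrame(
            scores,
            index=pd.Index(table.sample_ids, name="sample_id"),
            columns=[f"axis{i + 1}" for i in range(k)],
        ),
        "loadings": pd.DataFrame(
            Vt[:k].T,
            index=table.part_names,
            columns=[f"axis{i + 1}" for i in range(k)],
        ),
        "explained_variance": (s**2)[:k].tolist(),
        "explained_ratio": ((s**2) / total)[:k].tolist(),
        "total_variance": total,
    }
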