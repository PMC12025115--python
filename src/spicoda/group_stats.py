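"""Multivariate comparison of group compositions in ILR coordinates.

A one-way multivariate linear model is fitted to the ILR-transformed
compositions. The global null (all group centers equal) is tested with
Wilks' lambda (Rao's F approximation) or by permutation of the group
labels; pairwise group contrasts use Hotelling's T^2 with the pooled
within-group covariance. All statistics are invariant to the choice of
orthonormal ILR basis, so the (arbitrary) default pivot balances do not
affect inference.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .composition import CompositionTable, CompositionError, close_vector
from .transforms import ContrastMatrix, ilr, ilr_inv, make_sbp_basis

__all__ = [
    "IlrModelFit",
    "TestResult",
    "fit_ilr_model",
    "global_test",
    "pairwise_tests",
    "IlrManova",
]


@dataclasses.dataclass
class IlrModelFit:
    """One-way MANOVA fit on ILR coordinates.

    ``pooled_cov`` is the within-group covariance with denominator
    n - g (the residual degrees of freedom).
    """

    basis: ContrastMatrix
    group_names: list[str]
    group_means: np.ndarray  # g x (D-1)
    pooled_cov: np.ndarray  # (D-1) x (D-1)
    group_sizes: np.ndarray
    residual_df: int
    ilr_data: np.ndarray  # retained for permutation tests
    labels: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_coords(self) -> int:
        return self.group_means.shape[1]

    def group_center(self, name: str, kappa: float = 100.0) -> np.ndarray:
        """Back-transform a group's ILR mean to a closed composition.

        Equals the group's compositional center exactly (arithmetic mean
        in ILR coordinates is the geometric mean on the simplex).
        """
        i = self.group_names.index(name)
        return ilr_inv(self.group_means[i], self.basis, kappa=kappa)


@dataclasses.dataclass
class TestResult:
    statistic_name: str
    statistic: float
    df: tuple[float, float]
    p_value: float
    method: str  # "parametric" | "permutation"
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise CompositionError(f"p-value {self.p_value} outside [0, 1]")


def fit_ilr_model(
    table: CompositionTable,
    labels: Sequence[str] | pd.Series,
    basis: ContrastMatrix | None = None,
) -> IlrModelFit:
    """Fit the one-way multivariate model to ILR-transformed compositions."""
    if isinstance(labels, pd.Series):
        labels = labels.reindex(table.sample_ids).to_numpy()
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != table.n_samples:
        raise CompositionError("one label per sample required")
    if basis is None:
        basis = make_sbp_basis(table.part_names)
    y = ilr(table, basis)
    names = sorted(set(labels))
    if len(names) < 2:
        raise CompositionError("need at least 2 groups to compare")
    sizes = np.array([(labels == g).sum() for g in names])
    if (sizes < 2).any():
        small = names[int(np.argmin(sizes))]
        raise CompositionError(
            f"group {small!r} has fewer than 2 samples; use the permutation "
            "mode or merge groups"
        )
    means = np.vstack([y[labels == g].mean(axis=0) for g in names])
    n, p = y.shape
    g = len(names)
    resid = np.vstack([y[labels == gn] - means[i] for i, gn in enumerate(names)])
    pooled = resid.T @ resid / (n - g)
    return IlrModelFit(
        basis=basis,
        group_names=names,
        group_means=means,
        pooled_cov=pooled,
        group_sizes=sizes,
        residual_df=n - g,
        ilr_data=y,
        labels=labels,
    )


def _wilks_lambda(y: np.ndarray, labels: np.ndarray, names: Sequence[str]) -> float:
    grand = y.mean(axis=0)
    W = np.zeros((y.shape[1], y.shape[1]))
    B = np.zeros_like(W)
    for g in names:
        yg = y[labels == g]
        mg = yg.mean(axis=0)
        r = yg - mg
        W += r.T @ r
        d = (mg - grand)[:, None]
        B += len(yg) * (d @ d.T)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0 or sign_t <= 0:
        raise CompositionError(
            "singular scatter matrix: too few samples for the number of "
            "ILR coordinates"
        )
    return float(np.exp(logdet_w - logdet_t))


def _rao_f(lmbda: float, n: int, p: int, g: int) -> tuple[float, float, float]:
    """Rao's F approximation to the Wilks' lambda null distribution."""
    q = g - 1
    m = n - 1 - (p + q + 1) / 2
    denom = p * p + q * q - 5
    s = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - p * q / 2 + 1
    lam_s = lmbda ** (1 / s)
    f = (1 - lam_s) / lam_s * df2 / df1
    return f, df1, df2


def global_test(
    fit: IlrModelFit,
    mode: str = "parametric",
    n_perm: int = 9999,
    seed: int | None = None,
) -> TestResult:
    """Global test of equal group centers (compositional MANOVA).

    Parametric mode: Wilks' lambda with Rao's F approximation.
    Permutation mode: the same lambda recomputed under ``n_perm`` label
    shuffles; p = (1 + #{lambda_perm <= lambda_obs}) / (1 + n_perm).
    Invariant to the orthonormal ILR basis in both modes.
    """
    y, labels, names = fit.ilr_data, fit.labels, fit.group_names
    n, p = y.shape
    lmbda = _wilks_lambda(y, labels, names)
    if mode == "parametric":
        if fit.residual_df < p:
            raise CompositionError(
                "residual df < number of coordinates; use permutation mode"
            )
        f, df1, df2 = _rao_f(lmbda, n, p, len(names))
        pval = float(sps.f.sf(f, df1, df2))
        return TestResult("Wilks lambda", lmbda, (df1, df2), pval, "parametric")
    if mode == "permutation":
        if seed is None:
            raise CompositionError(
                "permutation mode requires an explicit seed (reproducibility)"
            )
        rng = np.random.default_rng(seed)
        count = 0
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            if _wilks_lambda(y, lab, names) <= lmbda:
                count += 1
        pval = (1 + count) / (1 + n_perm)
        return TestResult(
            "Wilks lambda", lmbda, (float("nan"), float("nan")), pval,
            "permutation", n_permutations=n_perm,
        )
    raise CompositionError(f"unknown mode {mode!r}")


def _hotelling(
    fit: IlrModelFit, ga: str, gb: str
) -> tuple[float, float, float, float]:
    ia, ib = fit.group_names.index(ga), fit.group_names.index(gb)
    na, nb = int(fit.group_sizes[ia]), int(fit.group_sizes[ib])
    d = fit.group_means[ia] - fit.group_means[ib]
    p = fit.n_coords
    nu = fit.residual_df
    # pinvh keeps the degenerate case (identical groups, zero scatter)
    # well-defined: d = 0 gives T^2 = 0 regardless of the covariance
    from scipy.linalg import pinvh

    t2 = (na * nb / (na + nb)) * float(d @ pinvh(fit.pooled_cov) @ d)
    f = t2 * (nu - p + 1) / (nu * p)
    return t2, f, p, nu - p + 1


def pairwise_tests(
    fit: IlrModelFit,
    adjust: str = "holm",
    mode: str = "parametric",
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hotelling's T^2 for every group pair, with multiplicity adjustment.

    Uses the pooled within-group covariance from the full fit. Returns a
    table with raw and adjusted p-values (Holm step-down by default).
    Permutation mode permutes labels within each pair's pooled samples.
    """
    from statsmodels.stats.multitest import multipletests

    pairs = list(itertools.combinations(fit.group_names, 2))
    rows = []
    for ga, gb in pairs:
        t2, f, p, df2 = _hotelling(fit, ga, gb)
        if mode == "parametric":
            if df2 <= 0:
                raise CompositionError(
                    "residual df too small for parametric T^2; use permutation"
                )
            pval = float(sps.f.sf(f, p, df2))
            rows.append((ga, gb, t2, f"({p:.0f}, {df2:.0f})", pval, mode))
        elif mode == "permutation":
            if seed is None:
                raise CompositionError(
                    "permutation mode requires an explicit seed (reproducibility)"
                )
            rng = np.random.default_rng(seed)
            mask = np.isin(fit.labels, [ga, gb])
            sub = fit.ilr_data[mask]
            sublab = fit.labels[mask].copy()
            obs = _two_group_t2(sub, sublab, ga, gb)
            count = 0
            for _ in range(n_perm):
                rng.shuffle(sublab)
                if _two_group_t2(sub, sublab, ga, gb) >= obs:
                    count += 1
            pval = (1 + count) / (1 + n_perm)
            rows.append((ga, gb, obs, "(perm)", pval, mode))
        else:
            raise CompositionError(f"unknown mode {mode!r}")
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "T2", "df", "p_raw", "method"]
    )
    if adjust == "none":
        out["p_adjusted"] = out["p_raw"]
    elif adjust in ("holm", "bonferroni"):
        out["p_adjusted"] = multipletests(out["p_raw"], method=adjust)[1]
    else:
        raise CompositionError(f"unknown adjustment {adjust!r}")
    return out


def _two_group_t2(y: np.ndarray, labels: np.ndarray, ga: str, gb: str) -> float:
    ya, yb = y[labels == ga], y[labels == gb]
    na, nb = len(ya), len(yb)
    d = ya.mean(axis=0) - yb.mean(axis=0)
    ra = ya - ya.mean(axis=0)
    rb = yb - yb.mean(axis=0)
    from scipy.linalg import pinvh

    pooled = (ra.T @ ra + rb.T @ rb) / (na + nb - 2)
    return (na * nb / (na + nb)) * float(d @ pinvh(pooled) @ d)


class IlrManova(BaseEstimator):
    """scikit-learn-style wrapper for the ILR MANOVA workflow.

    ``fit(X, y)`` takes compositions (CompositionTable or positive
    array) and group labels; fitted attributes expose the model, the
    global test and the pairwise table.
    """

    def __init__(
        self,
        mode: str = "parametric",
        adjust: str = "holm",
        n_perm: int = 9999,
        seed: int | None = None,
        partition=None,
    ):
        self.mode = mode
        self.adjust = adjust
        self.n_perm = n_perm
        self.seed = seed
        self.partition = partition

    def fit(self, X, y):
        if not isinstance(X, CompositionTable):
            X = np.asarray(X, dtype=float)
            X = CompositionTable(
                [f"s{i}" for i in range(X.shape[0])],
                [f"p{j}" for j in range(X.shape[1])],
                X,
            )
        basis = make_sbp_basis(X.part_names, self.partition)
        self.model_ = fit_ilr_model(X, y, basis)
        self.global_result_ = global_test(
            self.model_, mode=self.mode, n_perm=self.n_perm, seed=self.seed
        )
        self.pairwise_results_ = pairwise_tests(
            self.model_, adjust=self.adjust, mode=self.mode,
            n_perm=self.n_perm, seed=self.seed,
        )
        self.n_features_in_ = X.n_parts
        return self
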