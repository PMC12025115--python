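"""ILR MANOVA: model fit, global Wilks test, pairwise Hotelling tests."""

import numpy as np
import pandas as pd
import pytest

import spicoda as sp
from helpers import random_positive_table


@pytest.fixture
def two_group_table(rng):
    t = random_positive_table(rng, 30, 5)
    labels = np.array(["a"] * 15 + ["b"] * 15)
    return t, labels


def test_fit_group_mean_backtransforms_to_center(section_table):
    table, truth = section_table
    fit = sp.fit_ilr_model(table, truth)
    for g in fit.group_names:
        sub = table.select_samples(truth.to_numpy() == g)
        np.testing.assert_allclose(
            fit.group_center(g), sp.center(sub), atol=1e-9
        )


def test_fit_identical_rows_zero_covariance():
    vals = np.vstack([[10, 20, 70]] * 3 + [[30, 30, 40]] * 3).astype(float)
    t = sp.CompositionTable([f"s{i}" for i in range(6)], ["x", "y", "z"], vals)
    fit = sp.fit_ilr_model(t, ["a"] * 3 + ["b"] * 3)
    np.testing.assert_allclose(fit.pooled_cov, 0, atol=1e-20)
    assert fit.residual_df == 4


def test_fit_contract_errors(rng):
    t = random_positive_table(rng, 6, 4)
    with pytest.raises(sp.CompositionError, match="2 groups"):
        sp.fit_ilr_model(t, ["a"] * 6)
    with pytest.raises(sp.CompositionError, match="permutation"):
        sp.fit_ilr_model(t, ["a", "a", "a", "a", "a", "b"])


def test_global_test_matches_statsmodels_manova(two_group_table):
    """Wilks' lambda and its F approximation against an independent
    reference implementation."""
    sm_api = pytest.importorskip("statsmodels.multivariate.manova")
    t, labels = two_group_table
    fit = sp.fit_ilr_model(t, labels)
    res = sp.global_test(fit)
    y = fit.ilr_data
    df = pd.DataFrame(y, columns=[f"z{i}" for i in range(y.shape[1])])
    df["g"] = labels
    mv = sm_api.MANOVA.from_formula(
        " + ".join(df.columns[:-1]) + " ~ g", data=df
    )
    tab = mv.mv_test().results["g"]["stat"]
    assert res.statistic == pytest.approx(tab.loc["Wilks' lambda", "Value"], rel=1e-8)
    assert res.p_value == pytest.approx(tab.loc["Wilks' lambda", "Pr > F"], abs=1e-10)


def test_global_test_basis_invariance(two_group_table):
    t, labels = two_group_table
    pivot = sp.make_sbp_basis(t.part_names)
    other = sp.make_sbp_basis(
        t.part_names,
        [[1, 1, -1, -1, -1], [1, -1, 0, 0, 0], [0, 0, 1, -1, -1], [0, 0, 0, 1, -1]],
    )
    r1 = sp.global_test(sp.fit_ilr_model(t, labels, pivot))
    r2 = sp.global_test(sp.fit_ilr_model(t, labels, other))
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def test_forced_separation_tiny_p(rng):
    a = np.exp(rng.normal(0, 0.1, (20, 4)) + [3, 0, 0, 0])
    b = np.exp(rng.normal(0, 0.1, (20, 4)) + [0, 3, 0, 0])
    t = sp.CompositionTable([f"s{i}" for i in range(40)], list("wxyz"),
                            np.vstack([a, b]))
    fit = sp.fit_ilr_model(t, ["a"] * 20 + ["b"] * 20)
    assert sp.global_test(fit).p_value <= 1e-4


def test_permutation_agrees_with_parametric(two_group_table, rng):
    """Under approximately Gaussian ILR data the permutation p-value lies
    within Monte-Carlo error of the parametric one."""
    t, _ = two_group_table
    # moderate real separation so p is neither 0 nor 1
    shift = np.ones(4) * 0.35
    z = sp.ilr(t, sp.make_sbp_basis(t.part_names))
    z[:15] += shift / 2
    comp = sp.ilr_inv(z, sp.make_sbp_basis(t.part_names))
    t2 = sp.CompositionTable(t.sample_ids, t.part_names, comp)
    labels = ["a"] * 15 + ["b"] * 15
    fit = sp.fit_ilr_model(t2, labels)
    p_par = sp.global_test(fit).p_value
    p_perm = sp.global_test(fit, mode="permutation", n_perm=2000, seed=3).p_value
    mc_sd = np.sqrt(p_par * (1 - p_par) / 2000)
    assert abs(p_perm - p_par) < 4 * mc_sd + 1e-3


def test_permutation_requires_seed(two_group_table):
    t, labels = two_group_table
    fit = sp.fit_ilr_model(t, labels)
    with pytest.raises(sp.CompositionError, match="seed"):
        sp.global_test(fit, mode="permutation")
    with pytest.raises(sp.CompositionError, match="seed"):
        sp.pairwise_tests(fit, mode="permutation")


def test_permutation_p_floor(two_group_table):
    t, labels = two_group_table
    fit = sp.fit_ilr_model(t, labels)
    res = sp.global_test(fit, mode="permutation", n_perm=99, seed=1)
    assert res.p_value >= 1 / 100
    assert res.n_permutations == 99


def test_pairwise_identical_groups_t2_zero():
    vals = np.vstack([[10.0, 30.0, 60.0], [20.0, 30.0, 50.0]] * 4)
    t = sp.CompositionTable([f"s{i}" for i in range(8)], ["x", "y", "z"], vals)
    labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
    # groups a and b contain the same two compositions alternating
    fit = sp.fit_ilr_model(t, labels)
    pw = sp.pairwise_tests(fit)
    assert pw["T2"].iloc[0] == pytest.approx(0.0, abs=1e-18)
    assert pw["p_raw"].iloc[0] == pytest.approx(1.0)


def test_pairwise_all_pairs_reported_and_holm_monotone(section_table):
    table, truth = section_table
    fit = sp.fit_ilr_model(table, truth)
    pw = sp.pairwise_tests(fit, adjust="holm")
    assert len(pw) == 3
    assert (pw["p_adjusted"] >= pw["p_raw"] - 1e-300).all()
    bon = sp.pairwise_tests(fit, adjust="bonferroni")
    assert (bon["p_adjusted"] >= pw["p_adjusted"] - 1e-300).all()


def test_pairwise_t2_basis_invariance(section_table):
    table, truth = section_table
    b2 = sp.make_sbp_basis(
        table.part_names,
        [[1, 1, -1, -1, -1], [1, -1, 0, 0, 0], [0, 0, 1, -1, -1], [0, 0, 0, 1, -1]],
    )
    pw1 = sp.pairwise_tests(sp.fit_ilr_model(table, truth))
    pw2 = sp.pairwise_tests(sp.fit_ilr_model(table, truth, b2))
    np.testing.assert_allclose(pw1["T2"], pw2["T2"], atol=1e-8)


def test_ilr_manova_estimator(section_table):
    table, truth = section_table
    est = sp.IlrManova().fit(table, truth.to_numpy())
    assert est.global_result_.p_value <= 1e-4
    assert len(est.pairwise_results_) == 3
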