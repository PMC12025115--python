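"""Cluster summaries, ratio tables, ternary / biplot coordinates."""

import numpy as np
import pytest

import spicoda as sp
from helpers import quartiles_by_sorting, random_positive_table


def test_summary_identical_rows_degenerate():
    t = sp.CompositionTable(["a", "b", "c"], ["x", "y", "z"],
                            [[10.0, 30.0, 60.0]] * 3)
    s = sp.summarize_cluster(t, ["g"] * 3, "g")
    assert s.total_variance == pytest.approx(0.0, abs=1e-15)
    row = s.ratio_table.loc[("x", "y")]
    assert row["min"] == row["mean"] == row["max"]


def test_summary_empty_cluster_errors(small_table):
    with pytest.raises(sp.CompositionError, match="empty"):
        sp.summarize_cluster(small_table, ["g"] * 3, "other")


def test_ratio_table_mean_equals_center_ratio(rng):
    t = random_positive_table(rng, 12, 5)
    s = sp.summarize_cluster(t, ["g"] * 12, "g")
    c = s.center
    for (num, den), row in s.ratio_table.iterrows():
        assert row["mean"] == pytest.approx(c[num] / c[den], rel=1e-9)


def test_ratio_table_reciprocal_consistency(rng):
    t = random_positive_table(rng, 8, 4)
    s = sp.summarize_cluster(t, ["g"] * 8, "g")
    for (num, den), row in s.ratio_table.iterrows():
        rev = s.ratio_table.loc[(den, num)]
        assert rev["mean"] == pytest.approx(1 / row["mean"], rel=1e-12)
        assert rev["min"] == pytest.approx(1 / row["max"], rel=1e-12)
        assert rev["max"] == pytest.approx(1 / row["min"], rel=1e-12)


def test_ratio_summary_hand_example():
    t = sp.CompositionTable(["a", "b"], ["x", "y"],
                            [[2.0, 1.0], [8.0, 1.0]])
    out = sp.ratio_summary(t, ["g", "g"])
    row = out[(out["ratio"] == "x/y")].iloc[0]
    assert (row["min"], row["mean"], row["max"]) == pytest.approx((2, 4, 8))
    assert row["display"] == "2.0-4.0-8.0"


def test_summary_recovers_generator_center():
    """An SC II-like synthetic cluster reproduces its nominal center
    within 1.5 percentage points per part."""
    center, tv, _ = sp.SECTION_CENTERS["SC II"]
    spec = sp.ClusterSpec("SC II", sp.AMALGAMATED_PARTS, center, tv, 41)
    t, truth = sp.generate_clusters([spec], seed=9)
    s = sp.summarize_cluster(t, truth, "SC II")
    assert s.n == 41
    np.testing.assert_allclose(s.center.to_numpy(), center, atol=1.5)


def test_ternary_barycenter_and_oracle(rng):
    t = random_positive_table(rng, 10, 5)
    out = sp.ternary_coordinates(t, ("p0", "p1"), centered=False)
    # independent hand formula per sample
    for sid, row in out.iterrows():
        a, b, g = row["a"], row["b"], row["g"]
        assert row["x"] == pytest.approx(0.5 * (2 * b + g) / (a + b + g), abs=1e-12)
        assert row["y"] == pytest.approx(np.sqrt(3) / 2 * g / (a + b + g), abs=1e-12)
    # equal parts map to the triangle centroid
    eq = sp.CompositionTable(["s"], list("pqrs"), [[10.0, 10.0, 10.0, 10.0]])
    c = sp.ternary_coordinates(eq, ("p", "q"), centered=False)
    assert c["x"].iloc[0] == pytest.approx(0.5)
    assert c["y"].iloc[0] == pytest.approx(np.sqrt(3) / 6)


def test_ternary_centering_maps_center_to_barycenter(rng):
    t = random_positive_table(rng, 20, 5)
    out = sp.ternary_coordinates(t, ("p0", "p3"), centered=True)
    comp = out[["a", "b", "g"]].to_numpy()
    ctr = np.exp(np.log(comp).mean(axis=0))
    ctr /= ctr.sum()
    np.testing.assert_allclose(ctr, [1 / 3] * 3, atol=1e-12)


def test_ternary_contract_errors(small_table):
    with pytest.raises(sp.CompositionError, match="distinct"):
        sp.ternary_coordinates(small_table, ("Ca", "Ca"))


def test_boxstats_match_order_statistics_oracle(rng):
    t = random_positive_table(rng, 23, 4)
    out = sp.logratio_boxstats(t, ["g"] * 23)
    lm = np.log(t.values)
    row = out[out["ratio"] == "p0/p1"].iloc[0]
    q1, med, q3 = quartiles_by_sorting(lm[:, 0] - lm[:, 1])
    assert row["q1"] == pytest.approx(q1, abs=1e-12)
    assert row["median"] == pytest.approx(med, abs=1e-12)
    assert row["q3"] == pytest.approx(q3, abs=1e-12)
    iqr = q3 - q1
    lr = lm[:, 0] - lm[:, 1]
    inside = lr[(lr >= q1 - 1.5 * iqr) & (lr <= q3 + 1.5 * iqr)]
    assert row["whisker_lo"] == pytest.approx(inside.min())
    assert row["whisker_hi"] == pytest.approx(inside.max())


def test_boxstats_degenerate_all_equal():
    t = sp.CompositionTable(["a", "b", "c"], ["x", "y"],
                            [[30.0, 70.0]] * 3)
    out = sp.logratio_boxstats(t, ["g"] * 3)
    r = out.iloc[0]
    assert r["q1"] == r["median"] == r["q3"] == r["whisker_lo"] == r["whisker_hi"]
    assert r["n_outliers"] == 0


def test_biplot_one_dimensional_data_explains_everything(rng):
    base = np.array([1.0, 2.0, 4.0, 8.0])
    s = rng.normal(size=10)
    vals = np.exp(np.outer(s, np.log(base) - np.log(base).mean()) + 1)
    t = sp.CompositionTable([f"s{i}" for i in range(10)], list("wxyz"), vals)
    out = sp.logratio_biplot_coords(t)
    assert out["explained_ratio"][0] == pytest.approx(1.0, abs=1e-10)


def test_biplot_explained_sums_to_total_variance(rng):
    t = random_positive_table(rng, 15, 5)
    out = sp.logratio_biplot_coords(t)
    # matching convention: ddof=0 total variance
    assert out["total_variance"] == pytest.approx(
        sp.total_variance(t, ddof=0), abs=1e-10
    )
    w = sp.PartWeights.from_table(t)
    outw = sp.logratio_biplot_coords(t, w)
    assert outw["total_variance"] == pytest.approx(
        sp.total_variance(t, weights=w, ddof=0), abs=1e-10
    )


def test_biplot_sign_convention_deterministic(rng):
    t = random_positive_table(rng, 12, 5)
    a = sp.logratio_biplot_coords(t)
    b = sp.logratio_biplot_coords(t)
    np.testing.assert_array_equal(a["scores"].to_numpy(), b["scores"].to_numpy())
    for ax in a["loadings"].columns:
        j = a["loadings"][ax].abs().idxmax()
        assert a["loadings"].loc[j, ax] > 0


def test_biplot_degenerate_errors():
    t = sp.CompositionTable(["a", "b", "c"], ["x", "y", "z"],
                            [[10.0, 30.0, 60.0]] * 3)
    with pytest.raises(sp.CompositionError):
        sp.logratio_biplot_coords(t)
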