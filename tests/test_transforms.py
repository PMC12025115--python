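"""Log-ratio transforms: CLR, SBP/ILR bases, weighted coordinates."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone
from sklearn.pipeline import make_pipeline

import spicoda as sp
from spicoda.transforms import weighted_logratio_coords


def random_sbp(rng, d):
    """A random valid sequential binary partition as sign vectors."""
    groups = [list(range(d))]
    rows = []
    while groups:
        g = groups.pop()
        if len(g) == 1:
            continue
        split = rng.integers(1, len(g))
        perm = rng.permutation(g)
        left, right = sorted(perm[:split]), sorted(perm[split:])
        signs = [0] * d
        for i in left:
            signs[i] = 1
        for i in right:
            signs[i] = -1
        rows.append(signs)
        groups.extend([list(left), list(right)])
    return rows


def test_clr_hand_example():
    out = sp.clr(np.array([50.0, 30.0, 20.0]))
    np.testing.assert_allclose(out, [0.4757, -0.0351, -0.4406], atol=5e-4)
    assert out.sum() == pytest.approx(0.0, abs=1e-12)


def test_clr_uniform_is_zero():
    np.testing.assert_allclose(sp.clr(np.array([25.0] * 4)), np.zeros(4), atol=1e-14)


def test_clr_scale_invariance():
    x = np.array([12.0, 3.0, 55.0, 30.0])
    np.testing.assert_allclose(sp.clr(x), sp.clr(7.0 * x), atol=1e-12)


def test_clr_rejects_nonpositive(small_table):
    small_table.values[1, 2] = 0.0
    with pytest.raises(sp.CompositionError, match="s2"):
        sp.clr(small_table)


def test_pivot_basis_two_and_three_parts():
    b2 = sp.make_sbp_basis(["a", "b"])
    np.testing.assert_allclose(b2.basis, [[1 / np.sqrt(2), -1 / np.sqrt(2)]])
    b3 = sp.make_sbp_basis(["a", "b", "c"])
    np.testing.assert_allclose(
        b3.basis[0], [np.sqrt(2 / 3), -1 / np.sqrt(6), -1 / np.sqrt(6)], atol=1e-12
    )
    np.testing.assert_allclose(b3.basis[1], [0, 1 / np.sqrt(2), -1 / np.sqrt(2)],
                               atol=1e-12)


@given(st.integers(0, 10_000), st.integers(3, 8))
def test_any_sbp_gives_orthonormal_zero_sum_rows(seed, d):
    rng = np.random.default_rng(seed)
    cm = sp.make_sbp_basis([f"p{j}" for j in range(d)], random_sbp(rng, d))
    np.testing.assert_allclose(cm.basis @ cm.basis.T, np.eye(d - 1), atol=1e-10)
    np.testing.assert_allclose(cm.basis.sum(axis=1), 0, atol=1e-10)


def test_malformed_partition_rejected():
    with pytest.raises(sp.CompositionError):
        sp.make_sbp_basis(["a", "b", "c"], [[1, 1, 1], [0, 1, -1]])
    with pytest.raises(sp.CompositionError):
        sp.make_sbp_basis(["a", "b", "c"], [[1, -1, 0]])  # wrong row count


def test_ilr_two_part_closed_form():
    b = sp.make_sbp_basis(["a", "b"])
    z = sp.ilr(np.array([75.0, 25.0]), b)
    assert z[0] == pytest.approx(np.log(3) / np.sqrt(2), rel=1e-12)


def test_ilr_uniform_composition_is_origin():
    b = sp.make_sbp_basis(list("abcd"))
    np.testing.assert_allclose(sp.ilr(np.array([25.0] * 4), b), 0, atol=1e-13)


@given(st.integers(0, 10_000))
def test_ilr_isometry_with_aitchison_distance(seed):
    rng = np.random.default_rng(seed)
    d = int(rng.integers(3, 9))
    b = sp.make_sbp_basis([f"p{j}" for j in range(d)], random_sbp(rng, d))
    x, y = np.exp(rng.normal(size=(2, d)))
    dz = np.linalg.norm(sp.ilr(x, b) - sp.ilr(y, b))
    assert dz == pytest.approx(sp.aitchison_distance(x, y), abs=1e-10)


def test_ilr_inverse_roundtrip():
    b = sp.make_sbp_basis(list(sp.AMALGAMATED_PARTS))
    x = np.array([20.07, 46.05, 19.80, 1.60, 12.48])
    back = sp.ilr_inv(sp.ilr(x, b), b, kappa=100.0)
    np.testing.assert_allclose(back, x, atol=1e-9)


def test_ilr_part_mismatch_error(small_table):
    b = sp.make_sbp_basis(["w", "x", "y", "z"])
    with pytest.raises(sp.CompositionError, match="match"):
        sp.ilr(small_table, b)


def test_pairwise_logratios_values_and_antisymmetry(small_table):
    lr = sp.pairwise_logratios(small_table)
    np.testing.assert_allclose(lr["Ca/Mg"], -lr["Mg/Ca"], atol=1e-14)
    assert lr.loc["s1", "Ca/Mg"] == pytest.approx(np.log(40 / 5))


def test_subcompositional_coherence_of_ratios(seven_part_row):
    before = sp.pairwise_logratios(seven_part_row)["C/O"]
    after = sp.pairwise_logratios(sp.amalgamate(seven_part_row, {"Cl", "F", "P"}))["C/O"]
    np.testing.assert_allclose(before.to_numpy(), after.to_numpy(), atol=1e-14)


def test_clr_matches_skbio_reference(rng):
    skbio_comp = pytest.importorskip("skbio.stats.composition")
    x = np.exp(rng.normal(size=(6, 5)))
    x = x / x.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(sp.clr(x), skbio_comp.clr(x), atol=1e-12)


def test_uniform_weights_reduce_to_scaled_clr(rng):
    x = np.exp(rng.normal(size=(4, 5)))
    w = sp.PartWeights.uniform([f"p{j}" for j in range(5)])
    wc = weighted_logratio_coords(x, w)
    np.testing.assert_allclose(wc, sp.clr(x) / np.sqrt(5), atol=1e-12)


def test_part_weights_normalize_and_validate():
    w = sp.PartWeights(("a", "b"), np.array([2.0, 6.0]))
    np.testing.assert_allclose(w.w, [0.25, 0.75])
    with pytest.raises(sp.CompositionError):
        sp.PartWeights(("a", "b"), np.array([1.0, 0.0]))


def test_sklearn_transformer_contract(small_table):
    pipe = make_pipeline(sp.CLRTransformer())
    out = pipe.fit_transform(small_table.values)
    np.testing.assert_allclose(out.sum(axis=1), 0, atol=1e-12)
    ilr_t = sp.ILRTransformer().fit(small_table)
    assert ilr_t.basis_.parts == tuple(small_table.part_names)
    z = ilr_t.transform(small_table)
    assert z.shape == (3, 3)
    back = ilr_t.inverse_transform(z)
    np.testing.assert_allclose(
        back, small_table.values / small_table.values.sum(1, keepdims=True), atol=1e-9
    )
    clone(ilr_t)  # get_params/set_params round-trip
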