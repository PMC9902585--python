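"""Entropy / mutual-information core: closed forms, an independent plugin
oracle computed from the full joint distribution, and permutation behavior."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miscreen.infotheory import (
    DiscretizedVariable,
    discretize,
    entropy,
    mutual_information,
    normalized_mi,
    permutation_pvalue,
    permutation_screen,
    preprocess_for_entropy,
)


# ---------------------------------------------------------------------------
# independent oracle: MI straight from the empirical joint distribution,
# never through joint-entropy inclusion-exclusion
# ---------------------------------------------------------------------------


def _joint_probs(labels: list[np.ndarray]) -> dict[tuple, float]:
    n = len(labels[0])
    probs: dict[tuple, float] = {}
    for cell in zip(*labels):
        probs[cell] = probs.get(cell, 0.0) + 1.0 / n
    return probs


def _marginal(probs, axes):
    out: dict[tuple, float] = {}
    for cell, p in probs.items():
        key = tuple(cell[a] for a in axes)
        out[key] = out.get(key, 0.0) + p
    return out


def oracle_pairwise_mi(x, y):
    probs = _joint_probs([x, y])
    px, py = _marginal(probs, [0]), _marginal(probs, [1])
    return sum(
        p * np.log2(p / (px[(c[0],)] * py[(c[1],)])) for c, p in probs.items()
    )


def oracle_coinformation(x, y, z):
    """I(X;Y) - I(X;Y|Z), each term straight from the joint table."""
    probs = _joint_probs([x, y, z])
    pz = _marginal(probs, [2])
    pxz, pyz = _marginal(probs, [0, 2]), _marginal(probs, [1, 2])
    i_xy_given_z = sum(
        p * np.log2(p * pz[(c[2],)] / (pxz[(c[0], c[2])] * pyz[(c[1], c[2])]))
        for c, p in probs.items()
    )
    return oracle_pairwise_mi(x, y) - i_xy_given_z


def _dv(labels, n_levels=None, name="v"):
    labels = np.asarray(labels)
    return DiscretizedVariable(name, labels, n_levels or int(labels.max()) + 1)


# ---------------------------------------------------------------------------
# preprocessing and discretization
# ---------------------------------------------------------------------------


class TestPreprocess:
    def test_zeros_become_one_before_total_normalization(self):
        out = preprocess_for_entropy([0, 2, 2])
        np.testing.assert_allclose(out, np.log2([0.2, 0.4, 0.4]))

    def test_constant_input_maps_to_log_inverse_n(self):
        out = preprocess_for_entropy([3.0, 3.0, 3.0, 3.0])
        np.testing.assert_allclose(out, np.log2(0.25))

    def test_strictly_positive_input_untouched_by_zero_replacement(self):
        vals = np.array([1.5, 2.5, 6.0])
        np.testing.assert_allclose(
            preprocess_for_entropy(vals), np.log2(vals / vals.sum())
        )

    @pytest.mark.parametrize("bad", [[0.0, 0.0], [-1.0, 2.0]])
    def test_rejects_all_zero_or_negative(self, bad):
        with pytest.raises(ValueError):
            preprocess_for_entropy(bad)


class TestDiscretize:
    def test_balanced_bins_for_distinct_values(self):
        rng = np.random.default_rng(0)
        v = discretize(rng.permutation(100).astype(float), n_levels=10)
        assert np.bincount(v.labels).tolist() == [10] * 10

    def test_constant_vector_collapses_to_one_level(self):
        v = discretize(np.full(50, 3.3), n_levels=10)
        assert v.n_levels == 1
        assert v.provenance["collapsed"]
        assert entropy(v) == 0.0

    def test_monotone_transform_leaves_labels_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 3, 200)
        a = discretize(x, 8)
        b = discretize(np.log1p(x) ** 3, 8)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_monotone_in_values_and_ties_share_bins(self):
        x = np.array([5.0, 1.0, 5.0, 2.0, 9.0, 1.0])
        v = discretize(x, 3)
        assert v.labels[0] == v.labels[2] and v.labels[1] == v.labels[5]
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(v.labels[order]) >= 0)


# ---------------------------------------------------------------------------
# entropy and MI closed forms
# ---------------------------------------------------------------------------


class TestClosedForms:
    def test_uniform_four_level_entropy_is_two_bits(self):
        v = _dv(np.tile([0, 1, 2, 3], 25))
        assert entropy(v) == pytest.approx(2.0, abs=1e-12)

    def test_half_quarter_quarter_entropy(self):
        v = _dv([0, 0, 1, 2])
        assert entropy(v) == pytest.approx(1.5, abs=1e-12)

    def test_joint_entropy_of_variable_with_itself_is_marginal(self):
        rng = np.random.default_rng(2)
        v = _dv(rng.integers(0, 4, 100), 4)
        assert entropy(v, v) == pytest.approx(entropy(v), abs=1e-12)

    def test_identical_binary_uniform_mi_is_one_bit_and_nmi_one(self):
        v = _dv(np.tile([0, 1], 50), 2)
        mi = mutual_information(v, v)
        assert mi == pytest.approx(1.0, abs=1e-12)
        assert normalized_mi(mi, [entropy(v), entropy(v)]) == pytest.approx(1.0)

    def test_independent_balanced_pair_mi_is_zero(self):
        x = _dv([0, 0, 1, 1], 2)
        y = _dv([0, 1, 0, 1], 2)
        assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_xor_coinformation_is_minus_one_bit(self):
        rows = np.array(list(itertools.product([0, 1], repeat=2)))
        x, y = rows[:, 0], rows[:, 1]
        z = x ^ y
        ci = mutual_information(_dv(x, 2), _dv(y, 2), _dv(z, 2))
        assert ci == pytest.approx(-1.0, abs=1e-12)
        assert ci == pytest.approx(oracle_coinformation(x, y, z), abs=1e-12)

    def test_triple_identical_binary_uniform_nmi_is_one(self):
        v = _dv(np.tile([0, 1], 20), 2)
        ci = mutual_information(v, v, v)
        assert ci == pytest.approx(1.0, abs=1e-12)
        assert normalized_mi(ci, [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_nmi_zero_for_constant_marginal(self):
        assert normalized_mi(0.3, [0.0, 1.0]) == 0.0

    def test_rejects_unsupported_arity(self):
        v = _dv([0, 1, 0, 1], 2)
        with pytest.raises(ValueError):
            mutual_information(v)
        with pytest.raises(ValueError):
            mutual_information(v, v, v, v)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            entropy(_dv([0, 1], 2), _dv([0, 1, 0], 2))


# ---------------------------------------------------------------------------
# oracle equivalence and invariance properties
# ---------------------------------------------------------------------------


label_arrays = st.integers(2, 4).flatmap(
    lambda L: st.lists(st.integers(0, L - 1), min_size=8, max_size=40).map(
        lambda xs: (np.array(xs), L)
    )
)


class TestOracleEquivalence:
    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(label_arrays, label_arrays)
    def test_pairwise_matches_direct_plugin_and_nonnegative(self, a, b):
        (xa, la), (xb, lb) = a, b
        n = min(len(xa), len(xb))
        x, y = _dv(xa[:n], la), _dv(xb[:n], lb)
        mi = mutual_information(x, y)
        assert mi == pytest.approx(oracle_pairwise_mi(x.labels, y.labels), abs=1e-12)
        assert mi >= -1e-12

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(label_arrays, label_arrays, label_arrays)
    def test_triple_matches_direct_conditional_mi_decomposition(self, a, b, c):
        (xa, la), (xb, lb), (xc, lc) = a, b, c
        n = min(len(xa), len(xb), len(xc))
        x, y, z = _dv(xa[:n], la), _dv(xb[:n], lb), _dv(xc[:n], lc)
        ci = mutual_information(x, y, z)
        assert ci == pytest.approx(
            oracle_coinformation(x.labels, y.labels, z.labels), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(label_arrays, label_arrays, st.randoms(use_true_random=False))
    def test_relabeling_levels_changes_nothing(self, a, b, rnd):
        (xa, la), (xb, lb) = a, b
        n = min(len(xa), len(xb))
        x, y = _dv(xa[:n], la), _dv(xb[:n], lb)
        perm = list(range(la))
        rnd.shuffle(perm)
        x2 = _dv(np.array(perm)[x.labels], la)
        assert entropy(x2) == pytest.approx(entropy(x), abs=1e-12)
        assert mutual_information(x2, y) == pytest.approx(
            mutual_information(x, y), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(label_arrays, label_arrays)
    def test_subadditivity_of_joint_entropy(self, a, b):
        (xa, la), (xb, lb) = a, b
        n = min(len(xa), len(xb))
        x, y = _dv(xa[:n], la), _dv(xb[:n], lb)
        assert entropy(x, y) <= entropy(x) + entropy(y) + 1e-12


# ---------------------------------------------------------------------------
# permutation significance
# ---------------------------------------------------------------------------


class TestPermutation:
    def test_perfect_dependence_gives_minimal_p(self):
        rng = np.random.default_rng(3)
        x = _dv(rng.integers(0, 5, 200), 5)
        mi, p = permutation_pvalue(x, [x], n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)
        assert mi == pytest.approx(entropy(x), abs=1e-12)

    def test_observed_below_every_permutation_gives_p_one(self):
        # constant target: MI is 0 observed and 0 under every permutation
        x = _dv(np.zeros(60, dtype=int), 1)
        y = _dv(np.tile([0, 1, 2], 20), 3)
        _, p = permutation_pvalue(x, [y], n_perm=99, seed=1)
        assert p == 1.0

    def test_same_seed_reproduces_p_exactly(self):
        rng = np.random.default_rng(4)
        x = _dv(rng.integers(0, 4, 150), 4)
        y = _dv(rng.integers(0, 4, 150), 4)
        assert permutation_pvalue(x, [y], 199, seed=9) == permutation_pvalue(
            x, [y], 199, seed=9
        )

    def test_rejects_too_few_permutations(self):
        x = _dv([0, 1] * 30, 2)
        with pytest.raises(ValueError):
            permutation_pvalue(x, [x], n_perm=10, seed=0)

    def test_screen_agrees_with_single_gene_path(self):
        rng = np.random.default_rng(5)
        y1 = _dv(rng.integers(0, 5, 120), 5, "a1")
        y2 = _dv(rng.integers(0, 5, 120), 5, "a2")
        t = _dv(rng.integers(0, 5, 120), 5, "g")
        res = permutation_screen([t], y1, y2, n_perm=199, seed=42)
        mi1, p1 = permutation_pvalue(t, [y1], n_perm=199, seed=42)
        assert res["mi_1"][0] == pytest.approx(mi1, abs=1e-12)
        assert res["p_1"][0] == pytest.approx(p1)
        assert res["mi_3"][0] == pytest.approx(
            mutual_information(t, y1, y2), abs=1e-12
        )


def test_distinct_values_mode_gives_one_level_per_value():
    x = np.array([0.5, 0.5, 1.2, 3.0, 1.2])
    v = discretize(x, name="g", method="distinct")
    assert v.n_levels == 3
    assert v.labels[0] == v.labels[1] and v.labels[2] == v.labels[4]
    order = np.argsort(x, kind="stable")
    assert np.all(np.diff(v.labels[order]) >= 0)
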