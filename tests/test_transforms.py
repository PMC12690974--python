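import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simplexts.data_model import StudyDataset
from simplexts.transforms import (
    ZeroPolicy,
    aitchison_distance,
    alr_feature_names,
    alr_features,
    apply_zero_policy,
    clr,
    clr_inverse,
    fit_balance_tree,
    fit_zero_policy,
    flatten_series,
    plr_features,
    shannon_index,
)

from conftest import make_series


def compositions(min_d=3, max_d=8):
    return (
        st.lists(st.floats(0.01, 10.0), min_size=min_d, max_size=max_d)
        .map(lambda v: np.array(v) / np.sum(v))
    )


class TestZeroPolicy:
    def test_delta_is_half_the_training_minimum(self):
        rows = [[0.1, 0.6, 0.3], [0.5, 0.5, 0.0]]
        ds = StudyDataset(
            series=[make_series("a", rows, -1)],
            species_names=["x", "y", "z"],
            timepoint_names=["1", "2"],
        )
        assert fit_zero_policy(ds).delta == pytest.approx(0.05)

    def test_replacement_arithmetic(self):
        out = apply_zero_policy(np.array([0.5, 0.5, 0.0]), ZeroPolicy(0.05))
        np.testing.assert_allclose(out, [0.475, 0.475, 0.05])
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_zeros_untouched(self):
        x = np.array([0.2, 0.3, 0.5])
        np.testing.assert_array_equal(apply_zero_policy(x, ZeroPolicy(0.05)), x)

    def test_degenerate_zero_count_rejected(self):
        with pytest.raises(ValueError):
            apply_zero_policy(np.array([1.0, 0.0, 0.0]), ZeroPolicy(0.6))

    @given(compositions())
    @settings(max_examples=30, deadline=None)
    def test_simplex_and_ranking_preserved(self, x):
        x = x.copy()
        x[0] = 0.0
        x = x / x.sum()
        pol = ZeroPolicy(min(x[x > 0].min() / 2, 0.01))
        out = apply_zero_policy(x, pol)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out > 0)
        pos = x > 0
        assert np.array_equal(np.argsort(out[pos]), np.argsort(x[pos]))


class TestClr:
    def test_closed_form(self):
        np.testing.assert_allclose(
            clr(np.array([0.5, 0.25, 0.25])),
            [2 * np.log(2) / 3, -np.log(2) / 3, -np.log(2) / 3],
            atol=1e-12,
        )

    def test_uniform_maps_to_zero(self):
        np.testing.assert_allclose(clr(np.full(3, 1 / 3)), np.zeros(3), atol=1e-12)

    @given(compositions())
    @settings(max_examples=50, deadline=None)
    def test_round_trip_and_zero_sum(self, x):
        c = clr(x)
        assert abs(c.sum()) < 1e-10
        np.testing.assert_allclose(clr_inverse(c), x, atol=1e-10)
        np.testing.assert_allclose(clr(clr_inverse(c)), c, atol=1e-10)

    def test_softmax_translation_invariance(self):
        c = np.array([0.3, -1.2, 0.9])
        np.testing.assert_allclose(clr_inverse(c), clr_inverse(c + 7.5), atol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            clr(np.array([0.5, 0.5, 0.0]))


class TestFlatten:
    def test_uniform_two_timepoints(self):
        s = make_series("a", [[0.5, 0.5], [0.5, 0.5]], -1)
        np.testing.assert_allclose(flatten_series(s), [0.25] * 4)

    def test_sums_to_one_and_preserves_ratios(self):
        rows = np.random.default_rng(0).dirichlet(np.ones(4), size=3)
        s = make_series("a", rows, 1)
        X = flatten_series(s)
        assert X.shape == (12,)
        assert X.sum() == pytest.approx(1.0)
        # the 1/T factor cancels in within-vector ratios
        assert X[0] / X[5] == pytest.approx(rows[0, 0] / rows[1, 1])

    def test_missing_timepoint_rejected(self):
        s = make_series("a", np.full((2, 3), 1 / 3), -1, missing=[True, False])
        with pytest.raises(ValueError, match="missing"):
            flatten_series(s)


class TestAlr:
    def test_feature_count_formula(self):
        X = np.random.default_rng(0).dirichlet(np.ones(6))
        assert alr_features(X).shape == (15,)  # D(D-1)/2 for D=6
        assert len(alr_feature_names(list("abcdef"))) == 15

    def test_uniform_gives_zeros(self):
        np.testing.assert_allclose(alr_features(np.full(5, 0.2)), np.zeros(10), atol=1e-12)

    def test_antisymmetry(self):
        X = np.array([0.5, 0.3, 0.2])
        feats = alr_features(X)  # order: (0,1), (0,2), (1,2)
        assert feats[0] == pytest.approx(np.log(X[0] / X[1]))
        assert feats[0] == pytest.approx(-np.log(X[1] / X[0]))


class TestBalanceTree:
    def test_duplicate_columns_merge_first(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 1))
        mat = np.hstack([rng.normal(size=(20, 1)), base, base.copy()])
        tree = fit_balance_tree(mat)
        # the deepest (last BFS) node joins the identical columns 1 and 2
        left, right = tree.nodes[-1]
        assert {int(left[0]), int(right[0])} == {1, 2}

    def test_internal_node_count(self):
        mat = np.random.default_rng(0).normal(size=(10, 7))
        assert len(fit_balance_tree(mat).nodes) == 6

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(15, 5))
        t1 = fit_balance_tree(mat)
        t2 = fit_balance_tree(mat[rng.permutation(15)])
        for (l1, r1), (l2, r2) in zip(t1.nodes, t2.nodes):
            assert set(l1) == set(l2) and set(r1) == set(r2)

    def test_newick_serialization(self):
        mat = np.random.default_rng(2).normal(size=(12, 4))
        tree = fit_balance_tree(mat, leaf_names=["tp0:a", "tp0:b", "tp1:a", "tp1:b"])
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        assert nwk.count("(") == nwk.count(")")
        for name in ("tp0:a", "tp1:b"):
            assert name in nwk


class TestPlr:
    def test_uniform_composition(self):
        mat = np.random.default_rng(0).normal(size=(10, 4))
        tree = fit_balance_tree(mat)
        feats = plr_features(np.full(4, 0.25), tree)
        assert feats[0] == pytest.approx(np.log(0.25))
        np.testing.assert_allclose(feats[1:], np.zeros(3), atol=1e-12)

    def test_two_part_tree_equals_pairwise_log_ratio(self):
        mat = np.random.default_rng(1).normal(size=(10, 2))
        tree = fit_balance_tree(mat)
        X = np.array([2 / 3, 1 / 3])
        feats = plr_features(X, tree)
        assert feats.shape == (2,)
        assert abs(feats[1]) == pytest.approx(abs(np.log(X[0] / X[1])))

    def test_balances_invariant_to_scaling(self):
        rng = np.random.default_rng(4)
        tree = fit_balance_tree(rng.normal(size=(10, 5)))
        X = rng.dirichlet(np.ones(5))
        f1 = plr_features(X, tree)
        f2 = plr_features(X * 3.7, tree)
        np.testing.assert_allclose(f1[1:], f2[1:], atol=1e-12)

    def test_dimension_preserved(self):
        rng = np.random.default_rng(5)
        tree = fit_balance_tree(rng.normal(size=(10, 8)))
        assert plr_features(rng.dirichlet(np.ones(8)), tree).shape == (8,)

    def test_leaf_mismatch_rejected(self):
        tree = fit_balance_tree(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError):
            plr_features(np.full(5, 0.2), tree)


class TestDistanceAndDiversity:
    def test_aitchison_identity_symmetry_value(self):
        x = np.array([0.5, 0.25, 0.25])
        y = np.full(3, 1 / 3)
        assert aitchison_distance(x, x) == 0.0
        assert aitchison_distance(x, y) == aitchison_distance(y, x)
        assert aitchison_distance(x, y) == pytest.approx(0.5659, abs=1e-4)

    def test_shannon_values(self):
        assert shannon_index(np.full(5, 0.2)) == pytest.approx(np.log(5))
        assert shannon_index(np.array([1.0, 0.0, 0.0])) == 0.0
        assert shannon_index(np.array([0.5, 0.25, 0.25])) == pytest.approx(1.5 * np.log(2))
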