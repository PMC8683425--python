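"""Tests for the functional regression tree: splits, growth, pruning, prediction."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from funfor import (
    CurveMatrix,
    FunForParams,
    Grid,
    PredictorTable,
    best_split,
    candidate_splits,
    fit_tree,
    grow_tree,
    node_mean_curve,
    predict_tree,
    prune_tree,
    rss_f,
    split_criterion,
)
from funfor.exceptions import InvalidNodeError
from funfor.fpca import fit_fpca

SMALL_PARAMS = FunForParams(
    max_depth=4, min_node_size=5, mtry_fraction=1.0, l_fixed=2, n_basis=8
)


class TestNodeMath:
    def test_mean_of_single_member(self, grid20):
        c = np.sin(2 * np.pi * grid20.points)
        np.testing.assert_array_equal(node_mean_curve(c[None, :]), c)

    def test_mean_of_constant_pair(self, grid20):
        F = np.stack([np.zeros(20), np.ones(20)])
        np.testing.assert_allclose(node_mean_curve(F), 0.5)

    def test_mean_permutation_invariant(self, grid20):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((7, 20))
        perm = rng.permutation(7)
        np.testing.assert_allclose(node_mean_curve(F), node_mean_curve(F[perm]))

    def test_empty_node_rejected(self):
        with pytest.raises(InvalidNodeError):
            node_mean_curve(np.empty((0, 10)))

    def test_rss_zero_for_identical_members(self, grid20):
        F = np.tile(np.cos(2 * np.pi * grid20.points), (5, 1))
        assert rss_f(F, node_mean_curve(F), grid20) == pytest.approx(0.0, abs=1e-12)

    def test_rss_two_constant_curves(self, grid20):
        F = np.stack([np.zeros(20), np.ones(20)])
        assert rss_f(F, node_mean_curve(F), grid20) == pytest.approx(0.5)

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_rss_translation_invariant(self, shift):
        grid = Grid.uniform(20)
        rng = np.random.default_rng(1)
        F = rng.standard_normal((6, 20))
        g = shift * np.cos(2 * np.pi * grid.points)
        a = rss_f(F, node_mean_curve(F), grid)
        b = rss_f(F + g, node_mean_curve(F + g), grid)
        assert a == pytest.approx(b, abs=1e-8)

    def test_split_criterion_examples(self, grid20):
        assert split_criterion(np.ones(20), np.ones(20), grid20) == 0.0
        assert split_criterion(np.zeros(20), np.ones(20), grid20) == pytest.approx(1.0)

    def test_split_criterion_symmetric(self, grid20):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 20))
        assert split_criterion(a, b, grid20) == split_criterion(b, a, grid20)

    def test_decomposition_identity_random_nodes(self, grid20):
        """RSS(R) - RSS(R_L) - RSS(R_R) = (n_L n_R / n) phi on random partitions."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            m = int(rng.integers(4, 25))
            F = rng.standard_normal((m, 20))
            nL = int(rng.integers(1, m))
            L, R = F[:nL], F[nL:]
            lhs = (
                rss_f(F, node_mean_curve(F), grid20)
                - rss_f(L, node_mean_curve(L), grid20)
                - rss_f(R, node_mean_curve(R), grid20)
            )
            phi = split_criterion(node_mean_curve(L), node_mean_curve(R), grid20)
            assert lhs == pytest.approx(nL * (m - nL) / m * phi, abs=1e-8)


class TestCandidateSplits:
    def test_continuous_equipartition(self):
        x = np.array([0.0, 2.0, 5.0, 7.0, 11.0, 1.0, 3.0, 9.0])
        rules = candidate_splits(x, "continuous", n_split_points=10)
        np.testing.assert_allclose([r.threshold for r in rules], np.arange(1, 11))

    def test_categorical_three_levels(self):
        x = np.array([0, 1, 2, 0, 1, 2, 0], dtype=float)
        rules = candidate_splits(x, "categorical")
        assert [r.left_levels for r in rules] == [(0.0,), (0.0, 1.0), (0.0, 2.0)]

    def test_constant_column_empty(self):
        assert candidate_splits(np.full(10, 3.0), "continuous") == []
        assert candidate_splits(np.full(10, 1.0), "categorical") == []

    def test_min_node_size_filters(self):
        x = np.array([0.0, 0.1, 0.2, 10.0])
        rules = candidate_splits(x, "continuous", n_split_points=10, min_node_size=2)
        # any admissible threshold must leave >= 2 rows per side
        for r in rules:
            assert 2 <= np.sum(x < r.threshold) <= 2


class TestBestSplit:
    def test_perfect_binary_separator_chosen(self, two_group_data):
        curves, table = two_group_data
        F = curves.values  # raw curves as stand-in smooths
        rule = best_split(
            table.values,
            table.column_types,
            F,
            curves.grid,
            np.arange(table.p),
            min_node_size=5,
        )
        assert rule.predictor_index == 0
        assert rule.phi == pytest.approx(1.0, abs=0.05)

    def test_all_constant_columns_give_none(self, grid20):
        F = np.random.default_rng(0).standard_normal((10, 20))
        X = np.ones((10, 3))
        rule = best_split(X, ["continuous"] * 3, F, grid20, np.arange(3), 1)
        assert rule is None

    def test_agrees_with_bruteforce_scan(self, grid20):
        """Argmax over candidates matches an explicit double loop on <= 20 rows."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            m = int(rng.integers(8, 21))
            F = rng.standard_normal((m, 20))
            X = rng.standard_normal((m, 3))
            rule = best_split(
                X, ["continuous"] * 3, F, grid20, np.arange(3), min_node_size=1
            )
            best_phi = -1.0
            for j in range(3):
                for cand in candidate_splits(X[:, j], "continuous", 10, 1, j):
                    mask = X[:, j] < cand.threshold
                    phi = split_criterion(F[mask].mean(0), F[~mask].mean(0), grid20)
                    if phi > best_phi:
                        best_phi, best_j, best_mask = phi, j, mask
            assert rule.predictor_index == best_j
            # distinct thresholds can induce the same partition; compare partitions
            np.testing.assert_array_equal(
                X[:, rule.predictor_index] < rule.threshold, best_mask
            )
            assert rule.phi == pytest.approx(best_phi, abs=1e-9)


class TestGrowPredict:
    def test_single_strong_predictor_gives_depth_one_structure(self, two_group_data):
        curves, table = two_group_data
        params = FunForParams(
            max_depth=1, min_node_size=5, mtry_fraction=1.0, l_fixed=2, n_basis=8
        )
        tree = fit_tree(curves, table, params, np.random.default_rng(0))
        assert tree.n_splits == 1
        assert tree.growth_log[0][1].predictor_index == 0
        g0 = curves.values[table.values[:, 0] == 0].mean(axis=0)
        g1 = curves.values[table.values[:, 0] == 1].mean(axis=0)
        pred0 = predict_tree(tree, np.array([0.0, 0, 0, 0, 0]))
        pred1 = predict_tree(tree, np.array([1.0, 0, 0, 0, 0]))
        assert np.max(np.abs(pred0 - g0)) < 0.05
        assert np.max(np.abs(pred1 - g1)) < 0.05

    def test_max_depth_zero_is_stump(self, two_group_data):
        curves, table = two_group_data
        params = FunForParams(max_depth=0, mtry_fraction=1.0, l_fixed=2, n_basis=8)
        fpca = fit_fpca(curves, L_override=2, n_basis=8)
        tree = grow_tree(curves, fpca, table, params, np.random.default_rng(0))
        assert tree.n_splits == 0
        pred = predict_tree(tree, table.values[3])
        np.testing.assert_allclose(pred, fpca.smoothed_curves.mean(axis=0))

    def test_rows_partition_into_leaves(self, two_group_data):
        curves, table = two_group_data
        tree = fit_tree(curves, table, SMALL_PARAMS, np.random.default_rng(1))
        leaf_members = np.concatenate([lf.member_indices for lf in tree.leaves()])
        assert sorted(leaf_members.tolist()) == list(range(curves.n))

    def test_threshold_row_routes_right(self, grid20):
        """A row sitting exactly at the split threshold goes to the right child."""
        rng = np.random.default_rng(6)
        n = 30
        X = np.linspace(0, 11, n)[:, None]
        Y = (X >= 5.0).astype(float) * np.ones((n, 20)) + 0.01 * rng.standard_normal((n, 20))
        curves = CurveMatrix(Y, grid20)
        table = PredictorTable(X)
        params = FunForParams(
            max_depth=1, min_node_size=2, mtry_fraction=1.0, l_fixed=1, n_basis=8
        )
        tree = fit_tree(curves, table, params, rng)
        rule = tree.growth_log[0][1]
        at_threshold = predict_tree(tree, np.array([rule.threshold]))
        right_side = predict_tree(tree, np.array([rule.threshold + 100.0]))
        np.testing.assert_array_equal(at_threshold, right_side)

    def test_monotone_rss_with_depth_refit_off(self, two_group_data):
        curves, table = two_group_data
        fpca = fit_fpca(curves, L_override=2, n_basis=8)
        prev = np.inf
        for depth in range(4):
            params = FunForParams(
                max_depth=depth,
                min_node_size=5,
                mtry_fraction=1.0,
                refit_per_node=False,
                l_fixed=2,
                n_basis=8,
            )
            tree = grow_tree(curves, fpca, table, params, np.random.default_rng(2))
            total = 0.0
            for leaf in tree.leaves():
                F = fpca.smoothed_curves[leaf.member_indices]
                total += rss_f(F, leaf.mean_curve, curves.grid)
            assert total <= prev + 1e-9
            prev = total

    def test_growth_log_reproducible(self, two_group_data):
        curves, table = two_group_data
        t1 = fit_tree(curves, table, SMALL_PARAMS, np.random.default_rng(9))
        t2 = fit_tree(curves, table, SMALL_PARAMS, np.random.default_rng(9))
        assert json.dumps(t1.to_dict()) == json.dumps(t2.to_dict())

    def test_json_round_trip_preserves_predictions(self, two_group_data):
        from funfor.tree import FunctionalTree

        curves, table = two_group_data
        tree = fit_tree(curves, table, SMALL_PARAMS, np.random.default_rng(3))
        clone = FunctionalTree.from_dict(json.loads(json.dumps(tree.to_dict())))
        np.testing.assert_array_equal(
            tree.predict(table.values), clone.predict(table.values)
        )


class TestPruning:
    def test_null_response_prunes_to_stump(self, grid20):
        """Without predictor effects, CV picks the root stump in most seeds."""
        t = grid20.points
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 4))
            Y = np.sin(2 * np.pi * t)[None, :] + 0.5 * rng.standard_normal((40, 20))
            tree = fit_tree(
                CurveMatrix(Y, grid20), PredictorTable(X), SMALL_PARAMS, rng
            )
            pruned = prune_tree(
                tree, CurveMatrix(Y, grid20), PredictorTable(X), 5, rng
            )
            wins += pruned.n_splits == 0
        assert wins >= 16

    def test_single_strong_split_survives_pruning(self, grid20):
        t = grid20.points
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 4))
            X[:, 0] = (rng.random(40) > 0.5).astype(float)
            Y = (
                2.0 * X[:, 0][:, None]
                + np.sin(2 * np.pi * t)[None, :]
                + 0.2 * rng.standard_normal((40, 20))
            )
            cm, pt = CurveMatrix(Y, grid20), PredictorTable(X)
            pruned = prune_tree(fit_tree(cm, pt, SMALL_PARAMS, rng), cm, pt, 5, rng)
            wins += pruned.n_splits == 1
        assert wins >= 16

    def test_selected_subtree_minimizes_cv_path(self, two_group_data):
        curves, table = two_group_data
        rng = np.random.default_rng(4)
        tree = fit_tree(curves, table, SMALL_PARAMS, rng)
        pruned = prune_tree(tree, curves, table, 5, rng)
        path = pruned.cv_ise_path
        assert path[pruned.n_splits] == min(path)
        assert path[pruned.n_splits] <= path[-1]  # no worse than the full tree
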