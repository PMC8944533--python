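"""Gini tree: impurity arithmetic, greedy growth vs brute force, pruning,
stratified folds, and cross-validated selection."""

import numpy as np
import pytest

from parlourscore import (
    IndicatorTreeClassifier,
    PruningRule,
    TreeNode,
    ValidationError,
    best_split,
    cross_validate_select,
    gini_decrease,
    gini_impurity,
    grow_tree,
    predict,
    prune_tree,
    stratified_kfold,
)
from parlourscore.tree import predict_one, realized_decrease, tree_from_dict, tree_to_dict

from conftest import make_frame


def random_instance(seed, n=200, n_features=4, n_classes=3):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, n_features))
    y = rng.integers(0, n_classes, size=n)
    return X, y


def brute_force_best_split(X, y, available, n_classes=3):
    """Oracle: exhaustive evaluation of every candidate split."""
    parent = np.bincount(y, minlength=n_classes)
    results = []
    for f in available:
        mask = X[:, f] == 1
        if mask.all() or not mask.any():
            continue
        dec = gini_decrease(
            parent,
            np.bincount(y[~mask], minlength=n_classes),
            np.bincount(y[mask], minlength=n_classes),
        )
        results.append((f, dec))
    results = [(f, d) for f, d in results if d > 0]
    if not results:
        return None
    best_dec = max(d for _, d in results)
    # first feature in order achieving the maximum
    for f, d in results:
        if d == best_dec:
            return f, d
    raise AssertionError


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0, 0), 0.0), ((1, 1, 0), 0.5), ((2, 1, 1), 0.625)],
    )
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_raises(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0, 0))

    def test_three_class_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            g = gini_impurity(rng.integers(1, 100, size=3))
            assert 0.0 <= g <= 2.0 / 3.0 + 1e-12


class TestGiniDecrease:
    def test_perfect_split_of_half_impure_node(self):
        assert gini_decrease((4, 4, 0), (4, 0, 0), (0, 4, 0)) == pytest.approx(0.5)

    def test_uninformative_split(self):
        assert gini_decrease((2, 2, 0), (1, 1, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_empty_branch_rejected(self):
        with pytest.raises(ValidationError):
            gini_decrease((4, 4, 0), (4, 4, 0), (0, 0, 0))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            gini_decrease((4, 4, 0), (3, 0, 0), (0, 4, 0))

    def test_nonnegative_on_random_splits(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            left = rng.integers(0, 20, size=3)
            right = rng.integers(0, 20, size=3)
            if left.sum() == 0 or right.sum() == 0:
                continue
            assert gini_decrease(left + right, left, right) >= -1e-12


class TestBestSplit:
    def test_perfect_separator(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 0, 2, 2])
        feat, dec = best_split(X, y, (0, 1))
        assert feat == 0
        assert dec == pytest.approx(gini_impurity((2, 0, 2)))

    def test_constant_features_give_none(self):
        X = np.zeros((6, 4), dtype=int)
        y = np.array([0, 1, 2, 0, 1, 2])
        assert best_split(X, y, (0, 1, 2, 3)) is None

    @pytest.mark.parametrize("seed", range(100))
    def test_agrees_with_bruteforce_over_seeds(self, seed):
        X, y = random_instance(seed)
        got = best_split(X, y, (0, 1, 2, 3))
        expected = brute_force_best_split(X, y, (0, 1, 2, 3))
        if expected is None:
            assert got is None
        else:
            assert got[0] == expected[0]
            assert got[1] == pytest.approx(expected[1])


def assert_no_repeated_features(node, used=frozenset()):
    if node.is_leaf:
        return
    assert node.split_feature not in used
    assert_no_repeated_features(node.absent, used | {node.split_feature})
    assert_no_repeated_features(node.present, used | {node.split_feature})


def assert_counts_consistent(node):
    if node.is_leaf:
        return
    assert (node.absent.class_counts + node.present.class_counts == node.class_counts).all()
    assert_counts_consistent(node.absent)
    assert_counts_consistent(node.present)


def assert_greedy(node, X, y, available=(0, 1, 2, 3), idx=None):
    """Structural oracle: every internal node uses the brute-force-best
    split among features unused on its path."""
    if idx is None:
        idx = np.arange(len(y))
    if node.is_leaf:
        return
    expected = brute_force_best_split(X[idx], y[idx], available)
    assert expected is not None and node.split_feature == expected[0]
    mask = X[idx, node.split_feature] == 1
    remaining = tuple(f for f in available if f != node.split_feature)
    assert_greedy(node.absent, X, y, remaining, idx[~mask])
    assert_greedy(node.present, X, y, remaining, idx[mask])


class TestGrowTree:
    def test_pure_training_set_is_single_leaf(self):
        X = np.array([[0, 1, 0, 1]] * 5)
        tree = grow_tree(X, np.ones(5, dtype=int))
        assert tree.is_leaf and tree.predicted_class == 1

    def test_depth_bounded_and_features_unrepeated(self):
        for seed in range(20):
            X, y = random_instance(seed, n=120)
            tree = grow_tree(X, y)
            assert tree.depth <= 4
            assert_no_repeated_features(tree)
            assert_counts_consistent(tree)

    def test_greedy_growth_matches_bruteforce_everywhere(self):
        for seed in range(100):
            X, y = random_instance(seed, n=150)
            assert_greedy(grow_tree(X, y), X, y)

    def test_rule_based_structure_recovered(self):
        # class 2 iff SHH and at least two indicators; the root must pick the
        # maximal-decrease indicator and the tree stays within depth 4
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(2000, 4))
        y = np.where((X[:, 2] == 1) & (X.sum(axis=1) >= 2), 2, np.where(X[:, 0] == 1, 1, 0))
        tree = grow_tree(X, y)
        assert tree.depth <= 4
        assert_greedy(tree, X, y)
        # the fully grown tree reproduces the deterministic rule exactly
        assert (predict(tree, X) == y).all()

    def test_full_tree_predictions_equal_pattern_majority(self):
        # oracle: a maximum-depth tree over binary features predicts the
        # majority class of each observed indicator pattern (lowest class
        # index on ties)
        import pandas as pd

        for seed in (3, 7, 11):
            X, y = random_instance(seed, n=300)
            tree = grow_tree(X, y)
            pred = predict(tree, X)
            frame = pd.DataFrame(X, columns=list("abcd"))
            frame["y"] = y
            frame["pred"] = pred
            for _, grp in frame.groupby(list("abcd")):
                counts = np.bincount(grp["y"], minlength=3)
                assert (grp["pred"] == counts.argmax()).all()

    def test_training_accuracy_matches_sklearn_full_tree(self):
        # independent cross-check: scikit-learn's Gini tree grown to purity
        # achieves the same training accuracy (both realise the per-pattern
        # majority rule)
        from sklearn.tree import DecisionTreeClassifier

        for seed in (0, 1, 2):
            X, y = random_instance(seed, n=250)
            ours = (predict(grow_tree(X, y), X) == y).mean()
            sk = DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
            assert ours == pytest.approx(sk.score(X, y))


class TestPruneTree:
    def test_small_internal_node_collapsed(self):
        # exactly 20 observations may not split (the rule is strictly >20)
        X = np.array([[0, 0, 0, 0]] * 10 + [[1, 0, 0, 0]] * 10)
        y = np.array([0] * 10 + [2] * 10)
        grown = grow_tree(X, y)
        assert not grown.is_leaf
        pruned = prune_tree(grown, PruningRule())
        assert pruned.is_leaf

    def test_node_of_21_with_strong_split_retained(self):
        X = np.array([[0, 0, 0, 0]] * 10 + [[1, 0, 0, 0]] * 11)
        y = np.array([0] * 10 + [2] * 11)
        pruned = prune_tree(grow_tree(X, y), PruningRule())
        assert not pruned.is_leaf

    def test_exact_decrease_threshold_retained(self):
        # a split decreasing Gini by exactly the threshold survives
        X = np.array([[0, 0, 0, 0]] * 50 + [[1, 0, 0, 0]] * 50)
        y = np.array([0] * 45 + [1] * 5 + [0] * 40 + [1] * 10)
        grown = grow_tree(X, y)
        dec = realized_decrease(grown)
        pruned = prune_tree(grown, PruningRule(min_gini_decrease=dec))
        assert not pruned.is_leaf
        harsher = prune_tree(grown, PruningRule(min_gini_decrease=dec * 1.01))
        assert harsher.is_leaf

    def test_idempotent_on_conforming_tree(self):
        X, y = random_instance(2, n=500)
        pruned = prune_tree(grow_tree(X, y), PruningRule())
        again = prune_tree(pruned, PruningRule())
        assert tree_to_dict(again) == tree_to_dict(pruned)

    @pytest.mark.parametrize("seed", range(30))
    def test_pruned_trees_satisfy_both_criteria_structurally(self, seed):
        rule = PruningRule()
        X, y = random_instance(seed, n=400)
        pruned = prune_tree(grow_tree(X, y), rule)

        def check(node):
            if node.is_leaf:
                return
            assert node.n >= rule.min_node_size_to_split
            assert realized_decrease(node) >= rule.min_gini_decrease - 1e-12
            check(node.absent)
            check(node.present)

        check(pruned)

    def test_leaf_tie_break_toward_lower_class(self):
        node = TreeNode(class_counts=np.array([5, 5, 5]))
        assert node.predicted_class == 0


class TestPredict:
    def test_single_leaf(self):
        leaf = TreeNode(class_counts=np.array([3, 0, 0]))
        X = np.array([[0, 1, 0, 1], [1, 1, 1, 1]])
        assert predict(leaf, X).tolist() == [0, 0]

    def test_root_split_routing(self):
        tree = TreeNode(
            class_counts=np.array([5, 0, 5]),
            split_feature=2,
            absent=TreeNode(class_counts=np.array([5, 0, 0])),
            present=TreeNode(class_counts=np.array([0, 0, 5])),
        )
        assert predict_one(tree, [0, 0, 1, 0]) == 2
        assert predict_one(tree, [0, 0, 0, 0]) == 0

    def test_invalid_flag_raises(self):
        tree = TreeNode(
            class_counts=np.array([1, 0, 1]),
            split_feature=0,
            absent=TreeNode(class_counts=np.array([1, 0, 0])),
            present=TreeNode(class_counts=np.array([0, 0, 1])),
        )
        with pytest.raises(ValidationError):
            predict_one(tree, [2, 0, 0, 0])

    def test_study_preset_shh_absent_never_predicted_lame(self, study_sim):
        # qualitative reproduction: cows without a swollen heel/hock are
        # classified at most LS 1 by the selected tree
        cv = cross_validate_select(study_sim, seed=0)
        X = np.array([[sw, awd, 0, oh] for sw in (0, 1) for awd in (0, 1) for oh in (0, 1)])
        assert (cv.best_model.predict(X) <= 1).all()


class TestSerialization:
    def test_dict_round_trip(self):
        X, y = random_instance(4, n=300)
        tree = prune_tree(grow_tree(X, y), PruningRule())
        back = tree_from_dict(tree_to_dict(tree))
        assert tree_to_dict(back) == tree_to_dict(tree)
        assert (predict(back, X) == predict(tree, X)).all()

    def test_dot_labels_absent_present(self):
        from parlourscore import tree_to_dot

        X = np.array([[0, 0, 0, 0]] * 30 + [[0, 0, 1, 0]] * 30)
        y = np.array([0] * 30 + [2] * 30)
        dot = tree_to_dot(prune_tree(grow_tree(X, y), PruningRule()))
        assert 'label="absent", color=green' in dot
        assert 'label="present", color=red' in dot
        assert "SHH?" in dot


class TestStratifiedKfold:
    def test_exact_divisibility(self):
        y = np.array([0] * 4 + [1] * 4)
        folds = stratified_kfold(y, k=4, seed=0)
        for f in range(4):
            sel = y[folds == f]
            assert (sel == 0).sum() == 1 and (sel == 1).sum() == 1

    def test_study_scale_fold_sizes(self):
        # class counts (2873, 1119, 133): every fold holds ~1030 observations
        # leaving training complements of ~3095
        y = np.repeat([0, 1, 2], [2873, 1119, 133])
        folds = stratified_kfold(y, k=4, seed=1)
        sizes = np.bincount(folds, minlength=4)
        assert sizes.sum() == 4125
        assert all(1029 <= s <= 1034 for s in sizes)
        for cls, total in ((0, 2873), (1, 1119), (2, 133)):
            per_fold = np.bincount(folds[y == cls], minlength=4)
            assert per_fold.max() - per_fold.min() <= 1
            assert per_fold.sum() == total

    def test_seed_determinism(self):
        y = np.repeat([0, 1, 2], [40, 30, 10])
        a = stratified_kfold(y, k=4, seed=5)
        b = stratified_kfold(y, k=4, seed=5)
        c = stratified_kfold(y, k=4, seed=6)
        assert (a == b).all()
        assert not (a == c).all()

    def test_rare_class_warns(self):
        y = np.array([0] * 20 + [2] * 2)
        with pytest.warns(UserWarning, match="fewer than"):
            stratified_kfold(y, k=4, seed=0)


class TestCrossValidateSelect:
    def test_noiseless_rule_gives_perfect_folds(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 2, size=(2000, 4))
        ls = np.where((X[:, 2] == 1) & (X.sum(axis=1) >= 2), 2, X[:, 0])
        frame = make_frame(ls, sw=X[:, 0], awd=X[:, 1], shh=X[:, 2], oh=X[:, 3])
        cv = cross_validate_select(frame, seed=3)
        assert cv.fold_accuracies == pytest.approx([1.0, 1.0, 1.0, 1.0])

    def test_k2_runs_two_classifiers(self):
        frame = make_frame([0, 0, 1, 1, 0, 1, 0, 1, 0, 1], sw=[0, 0, 1, 1, 0, 1, 0, 1, 0, 1])
        cv = cross_validate_select(frame, k=2, seed=0)
        assert len(cv.fold_models) == 2
        assert len(cv.fold_confusions) == 2

    def test_study_preset_selected_accuracy_above_090(self, study_sim):
        cv = cross_validate_select(study_sim, seed=1)
        assert cv.best_accuracy > 0.90
        assert cv.best_fold == int(np.argmax(cv.fold_accuracies))

    def test_tie_break_lowest_fold_index(self):
        accs = [0.9, 0.95, 0.95, 0.8]
        assert int(np.argmax(accs)) == 1  # numpy argmax takes the first max

    def test_beats_majority_baseline_on_most_replicates(self):
        # sanity floor: the selected classifier is at least as accurate as a
        # single-leaf majority vote on >= 95% of replicates
        wins = 0
        reps = 40
        for seed in range(reps):
            rng = np.random.default_rng(100 + seed)
            n = 600
            ls = rng.choice([0, 1, 2], size=n, p=[0.6, 0.3, 0.1])
            p = np.array([[0.05] * 4, [0.3, 0.3, 0.1, 0.2], [0.4, 0.45, 0.75, 0.4]])
            X = (rng.random((n, 4)) < p[ls]).astype(int)
            frame = make_frame(ls, sw=X[:, 0], awd=X[:, 1], shh=X[:, 2], oh=X[:, 3])
            cv = cross_validate_select(frame, seed=seed)
            test_idx = cv.fold_assignment == cv.best_fold
            train_majority = np.bincount(ls[~test_idx], minlength=3).argmax()
            baseline = (ls[test_idx] == train_majority).mean()
            if cv.best_accuracy >= baseline:
                wins += 1
        assert wins >= 0.95 * reps


class TestEstimatorApi:
    def test_get_set_params_round_trip(self):
        clf = IndicatorTreeClassifier(min_samples_split=30)
        params = clf.get_params()
        assert params["min_samples_split"] == 30
        clf.set_params(min_impurity_decrease=0.01)
        assert clf.min_impurity_decrease == 0.01

    def test_fitted_attributes(self):
        X, y = random_instance(0)
        clf = IndicatorTreeClassifier().fit(X, y)
        assert hasattr(clf, "tree_")
        assert clf.n_features_in_ == 4
        assert clf.classes_.tolist() == [0, 1, 2]

    def test_dataframe_input_records_feature_names(self, study_sim):
        X = study_sim[["sw", "awd", "shh", "oh"]].head(200)
        y = np.minimum(study_sim["ls"].head(200).to_numpy(), 2)
        clf = IndicatorTreeClassifier().fit(X, y)
        assert clf.feature_names_in_.tolist() == ["sw", "awd", "shh", "oh"]

    def test_rejects_nonbinary_features(self):
        with pytest.raises(ValidationError):
            IndicatorTreeClassifier().fit(np.array([[0, 2, 0, 0]]), [0])

    def test_constrained_growth_mode(self):
        X, y = random_instance(6, n=400)
        pruned = IndicatorTreeClassifier(growth="prune").fit(X, y)
        constrained = IndicatorTreeClassifier(growth="constrained").fit(X, y)
        rule = PruningRule()
        for clf in (pruned, constrained):

            def check(node):
                if node.is_leaf:
                    return
                assert node.n >= rule.min_node_size_to_split
                check(node.absent)
                check(node.present)

            check(clf.tree_)

    def test_sklearn_cross_val_score_integration(self):
        from sklearn.model_selection import cross_val_score

        X, y = random_instance(8, n=200, n_classes=2)
        y = (X[:, 0] | X[:, 1]) ^ (y * 0)  # deterministic binary target
        scores = cross_val_score(IndicatorTreeClassifier(min_samples_split=5), X, y, cv=3)
        assert (scores == 1.0).all()
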