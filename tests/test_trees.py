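import numpy as np
import pandas as pd
import pytest

from nkaminer import (
    CRITERIA,
    AttributeTable,
    TreeParams,
    best_split,
    evaluate,
    extract_routes,
    induce_forest,
    induce_random_tree,
    induce_stump,
    induce_tree,
    run_sweep,
)

from oracles import enumerate_splits, naive_entropy


def frame(columns, y):
    X = pd.DataFrame(columns)
    return X, np.asarray(y)


class TestBestSplit:
    def test_perfect_binary_split(self):
        thr, score = best_split(np.array([1.0, 1, 2, 2]), np.array(list("AABB")),
                                "information_gain")
        assert thr == 1.5 and score == pytest.approx(1.0)

    def test_constant_attribute_means_no_split(self):
        thr, score = best_split(np.array([3.0, 3, 3, 3]), np.array(list("AABB")),
                                "information_gain")
        assert thr is None and score == 0.0

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_matches_exhaustive_enumeration(self, criterion):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.integers(0, 5, size=8).astype(float)
            labels = rng.choice(list("ABC"), size=8)
            if len(set(labels)) < 2:
                continue
            thr, score = best_split(values, labels, criterion)
            e_thr, e_score = enumerate_splits(values, labels, criterion)
            assert score == pytest.approx(e_score, abs=1e-9)
            if e_thr is not None:
                assert thr == pytest.approx(e_thr)

    @pytest.mark.parametrize("criterion", CRITERIA)
    def test_score_zero_for_class_independent_attribute(self, criterion):
        values = np.array([1.0, 2, 1, 2, 1, 2])
        labels = np.array(list("ABABAB"))
        # attribute value identical within each label pattern -> no signal
        _, score = best_split(np.array([5.0] * 6), labels, criterion)
        assert score == 0.0
        _, score2 = best_split(values, np.array(list("AABBAB")), criterion)
        assert score2 >= 0.0


class TestInduction:
    def test_separable_gives_depth_one_and_perfect_training(self):
        X, y = frame({"a": [0, 0, 1, 1.0], "b": [5, 6, 5, 6.0]}, list("AABB"))
        tree = induce_tree(X, y)
        assert tree.root_attribute == "a"
        assert not tree.root.left.is_leaf or tree.root.left.is_leaf
        assert tree.predict_labels(X.to_numpy()) == list(y)
        assert len(tree.leaves()) == 2

    @pytest.mark.parametrize("criterion", ["information_gain", "gini_index", "gain_ratio"])
    def test_consistent_table_reaches_full_training_accuracy(self, criterion):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        y = rng.choice(list("ABC"), size=30)
        params = TreeParams(max_depth=None, minimal_gain=None, min_leaf=1)
        tree = induce_tree(X, y, criterion, params)
        assert tree.predict_labels(X.to_numpy()) == list(y)

    def test_gain_ratio_identity_at_chosen_split(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=20)
        labels = rng.choice(list("AB"), size=20)
        thr, gr = best_split(values, labels, "gain_ratio")
        if thr is None:
            pytest.skip("degenerate draw")
        _, ig = enumerate_splits(values, labels, "information_gain")
        left = [l for v, l in zip(values, labels) if v <= thr]
        pl = len(left) / len(labels)
        split_info = naive_entropy(["L"] * len(left) + ["R"] * (len(labels) - len(left)))
        ig_at_thr = (naive_entropy(list(labels))
                     - pl * naive_entropy(left)
                     - (1 - pl) * naive_entropy([l for v, l in zip(values, labels) if v > thr]))
        assert gr == pytest.approx(ig_at_thr / split_info, abs=1e-9)
        assert gr <= ig / min(pl and split_info or 1.0, split_info) + 1e-9

    def test_single_class_table_gives_single_leaf(self):
        X, y = frame({"a": [1.0, 2, 3]}, list("AAA"))
        tree = induce_tree(X, y)
        assert tree.root.is_leaf and tree.predict_labels(X.to_numpy()) == ["A", "A", "A"]

    def test_paper_shaped_prokaryote_route(self):
        """A three-step route (count_GC <= 2.5, ratio_A_C <= 5.647,
        length <= 973) isolates the prokaryote-like rows."""
        cols = {
            "length": [946, 946, 1000, 1000, 946, 1000, 946, 1000.0],
            "count_GC": [2, 2, 2, 2, 2, 2, 3, 3.0],
            "ratio_A_C": [5.294, 5.294, 5.294, 5.294, 6.0, 6.0, 5.294, 6.0],
        }
        y = ["prokaryote"] * 2 + ["fungi"] * 2 + ["Protista"] * 2 + ["vertebrate"] * 2
        tree = induce_tree(pd.DataFrame(cols), np.array(y))
        routes = extract_routes(tree)
        prok = next(r for r in routes if r.klass == "prokaryote")
        assert [(a, op) for a, op, _ in prok.conjuncts] == [
            ("count_GC", "<="), ("ratio_A_C", "<="), ("length", "<="),
        ]
        assert [t for _, _, t in prok.conjuncts] == pytest.approx([2.5, 5.647, 973.0])


class TestFlavors:
    def separable(self):
        return frame({"a": [0, 0, 0, 1, 1, 1.0], "b": [1, 2, 3, 1, 2, 3.0]},
                     list("AAABBB"))

    def test_stump_equals_tree_on_one_attribute_data(self):
        X, y = self.separable()
        stump = induce_stump(X, y)
        tree = induce_tree(X, y)
        assert stump.root.threshold == tree.root.threshold
        assert stump.predict_labels(X.to_numpy()) == tree.predict_labels(X.to_numpy())

    def test_forest_b1_reduces_to_tree_on_its_bootstrap(self):
        X, y = self.separable()
        params = TreeParams(forest_size=1, subset_size=2)
        forest = induce_forest(X, y, params=params, seed=11)
        rng = np.random.default_rng(11)
        idx = rng.integers(0, len(y), size=len(y))
        boot_tree = induce_tree(X.iloc[idx], y[idx])
        assert forest.trees[0].predict_labels(X.to_numpy()) == boot_tree.predict_labels(
            X.to_numpy()
        )

    def test_forest_seed_determinism_and_majority_stability(self):
        X, y = self.separable()
        params = TreeParams(forest_size=15)
        f1 = induce_forest(X, y, params=params, seed=4)
        f2 = induce_forest(X, y, params=params, seed=4)
        assert [t.to_text() for t in f1.trees] == [t.to_text() for t in f2.trees]
        f3 = induce_forest(X, y, params=params, seed=5)
        assert f3.predict_labels(X.to_numpy()) == f1.predict_labels(X.to_numpy()) == list(y)

    def test_random_tree_uses_feature_subsets_deterministically(self):
        X, y = self.separable()
        t1 = induce_random_tree(X, y, seed=2)
        t2 = induce_random_tree(X, y, seed=2)
        assert t1.to_text() == t2.to_text()


class TestEvaluate:
    def test_perfectly_separable_scores_100(self):
        X, y = frame({"a": [0, 0, 0, 0, 1, 1, 1, 1.0]}, list("AAAABBBB"))
        for model in ("decision_tree", "decision_stump"):
            assert evaluate(model, X, y, folds=2, seed=0) == 100.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        accs = []
        for rep in range(20):
            y = np.array(["A", "B"] * 30)
            rng.shuffle(y)
            accs.append(evaluate("decision_tree", X, y, folds=5, seed=rep))
        mean = float(np.mean(accs))
        assert 35.0 < mean < 65.0  # binomial noise around 50

    def test_constant_attribute_gives_majority_baseline(self):
        X, y = frame({"a": [1.0] * 9}, list("AAAAAABBB"))
        acc = evaluate("decision_tree", X, y, folds=3, seed=0)
        assert acc == pytest.approx(100 * 6 / 9, abs=1e-9)

    def test_small_class_triggers_fold_advice(self):
        X, y = frame({"a": [0, 0, 0, 1, 1.0]}, list("AAABB"))
        with pytest.raises(ValueError, match="folds"):
            evaluate("decision_tree", X, y, folds=3, seed=0)


class TestSweep:
    def tiny_datasets(self):
        rng = np.random.default_rng(0)
        y = ["A"] * 6 + ["B"] * 6
        data = pd.DataFrame({
            "sep": [0.0] * 6 + [1.0] * 6,
            "noise": rng.normal(size=12),
        }, index=[f"s{i}" for i in range(12)])
        labels = pd.DataFrame({"group": y, "isoform": [""] * 12}, index=data.index)
        t = AttributeTable(data=data, labels=labels, inventory_version="test-v0")
        return {"fcd": t, "alt": t.subset(["sep"])}

    def test_cell_count_and_determinism(self):
        ds = self.tiny_datasets()
        params = TreeParams(forest_size=5)
        s1 = run_sweep(ds, "group", folds=2, seed=9, params=params)
        s2 = run_sweep(ds, "group", folds=2, seed=9, params=params)
        assert s1.n_cells == 4 * 4 * 2
        pd.testing.assert_frame_equal(s1.performance, s2.performance)
        assert s1.best_cells == s2.best_cells

    def test_single_dataset_gives_16_cells(self):
        ds = {"fcd": self.tiny_datasets()["fcd"]}
        s = run_sweep(ds, "group", folds=2, seed=1, params=TreeParams(forest_size=3))
        assert s.n_cells == 16
        assert s.performance.to_numpy().min() >= 0
        assert s.performance.to_numpy().max() <= 100

    def test_empty_dataset_list_rejected(self):
        with pytest.raises(ValueError):
            run_sweep({}, "group", folds=2, seed=0)


class TestRoutes:
    def test_depth_one_tree_has_two_routes(self):
        X = pd.DataFrame({"a": [0, 0, 1, 1.0]})
        tree = induce_tree(X, np.array(list("AABB")))
        routes = extract_routes(tree)
        assert len(routes) == len(tree.leaves()) == 2
        assert {r.klass for r in routes} == {"A", "B"}

    def test_routes_ordered_by_coverage(self):
        X = pd.DataFrame({"a": [0, 0, 0, 0, 0, 1.0], "b": [0, 0, 0, 0, 0, 9.0]})
        tree = induce_tree(X, np.array(list("AAAAAB")))
        routes = extract_routes(tree)
        assert routes[0].n_rows >= routes[-1].n_rows
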