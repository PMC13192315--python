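"""Surrogate forests: hyperparameters, adjusted agreement, SMD, MAA."""

import numpy as np
import pytest
from scipy import stats

from sers_cooccur.errors import CountError, SelectionError, StratificationError
from sers_cooccur.forest_smd import (
    ForestParams,
    SplitNode,
    Surrogate,
    SurrogateForest,
    SurrogateTree,
    adjusted_agreement,
    compute_mtry,
    compute_s,
    evaluate,
    fit_forest,
    mean_adjusted_agreement,
    maa_matrix,
    pick_representatives,
    smd_threshold,
    split_train_test,
    surrogate_minimal_depth,
)
from sers_cooccur.spectra_io import SpectraSet, WavenumberAxis


def matrix_set(matrix, labels):
    axis = WavenumberAxis(400.0 + 2.0 * np.arange(matrix.shape[1]))
    return SpectraSet(axis, matrix, np.asarray(labels, dtype=object))


class TestHyperparameters:
    @pytest.mark.parametrize("p,expected", [(880, 161), (16, 8), (1, 1), (2, 1)])
    def test_mtry_formula(self, p, expected):
        assert compute_mtry(p) == expected

    def test_mtry_zero_rejected(self):
        with pytest.raises(CountError):
            compute_mtry(0)

    @pytest.mark.parametrize("p,expected", [(880, 88), (10, 1), (9, 1), (25, 2)])
    def test_s_formula(self, p, expected):
        assert compute_s(p) == expected

    def test_s_small_p_rejected(self):
        with pytest.raises(CountError):
            compute_s(1)


class TestSplit:
    def test_exact_fractions_per_class(self):
        rng = np.random.default_rng(0)
        sset = matrix_set(rng.normal(size=(20, 4)), ["a"] * 10 + ["b"] * 10)
        train, test = split_train_test(sset, 0.8, seed=1)
        assert sum(train.labels == "a") == 8 and sum(train.labels == "b") == 8
        assert sum(test.labels == "a") == 2 and sum(test.labels == "b") == 2

    def test_partition_disjoint_exhaustive_deterministic(self):
        rng = np.random.default_rng(1)
        matrix = rng.normal(size=(30, 4))
        sset = matrix_set(matrix, ["a"] * 15 + ["b"] * 15)
        t1, s1 = split_train_test(sset, 0.8, seed=7)
        t2, s2 = split_train_test(sset, 0.8, seed=7)
        np.testing.assert_array_equal(t1.matrix, t2.matrix)
        np.testing.assert_array_equal(s1.matrix, s2.matrix)
        combined = np.vstack([t1.matrix, s1.matrix])
        assert combined.shape[0] == 30
        # every original row appears exactly once across the two parts
        order = np.lexsort(matrix.T)
        combined_order = np.lexsort(combined.T)
        np.testing.assert_array_equal(matrix[order], combined[combined_order])

    def test_singleton_class_rejected(self):
        sset = matrix_set(np.zeros((3, 4)), ["a", "a", "b"])
        with pytest.raises(StratificationError):
            split_train_test(sset, 0.8, seed=0)


def brute_force_adjusted_agreement(x, left_mask):
    """Exhaustive threshold search on a single candidate variable."""
    m = x.size
    tot_left = left_mask.sum()
    baseline = max(tot_left, m - tot_left) / m
    values = np.unique(x)
    if values.size < 2:
        return None
    best = (-np.inf, None, None)
    for t in (values[:-1] + values[1:]) / 2:
        low = x <= t
        a_norm = (left_mask[low].sum() + (~left_mask[~low]).sum()) / m
        a_flip = ((~left_mask[low]).sum() + left_mask[~low].sum()) / m
        for a, flip in ((a_norm, False), (a_flip, True)):
            if a > best[0]:
                best = (a, t, flip)
    a, t, flip = best
    return t, flip, (a - baseline) / (1 - baseline)


class TestAdjustedAgreement:
    def test_duplicate_candidate_is_perfect_surrogate(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        left = x <= np.median(x)
        thr, flipped, value = adjusted_agreement(x, left)
        assert value == 1.0 and not flipped

    def test_negated_candidate_perfect_with_flip(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        left = x <= 0.3
        thr, flipped, value = adjusted_agreement(-x, left)
        assert value == 1.0 and flipped

    def test_constant_candidate_excluded(self):
        left = np.array([True, True, False, False])
        assert adjusted_agreement(np.ones(4), left) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40).round(1)  # ties on purpose
        primary = rng.normal(size=40)
        left = primary <= np.quantile(primary, 0.4)
        got = adjusted_agreement(x, left)
        want = brute_force_adjusted_agreement(x, left)
        assert got[2] == pytest.approx(want[2], abs=1e-12)

    def test_independent_noise_null_matches_bridge_asymptotics(self):
        # For an independent candidate at a balanced node, the cumulative
        # agreement path is a random bridge; with orientation flips the best
        # cut behaves like sup|B| of a Brownian bridge, so
        # E[A] ~ 2 E[sup|B|] / sqrt(m) = 2 sqrt(pi/2) ln 2 / sqrt(m).
        rng = np.random.default_rng(4)
        m = 200
        left = np.zeros(m, dtype=bool)
        left[: m // 2] = True
        values = []
        for _ in range(1000):
            x = rng.uniform(size=m)
            _, _, value = adjusted_agreement(x, left)
            values.append(value)
        expected = 2.0 * np.sqrt(np.pi / 2.0) * np.log(2.0) / np.sqrt(m)
        assert abs(np.mean(values) - expected) < 0.015
        assert np.mean(values) <= 0.15  # small under the null in absolute terms


class TestFitForest:
    def test_perfectly_separable_variable(self):
        rng = np.random.default_rng(5)
        n = 60
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        matrix = rng.normal(size=(n, 5))
        matrix[:, 2] = np.where(np.array(labels) == "a", -5.0, 5.0) + rng.normal(
            0, 0.1, n
        )
        sset = matrix_set(matrix, labels)
        train, test = split_train_test(sset, 0.8, seed=0)
        forest = fit_forest(train, ForestParams(num_trees=25, seed=0))
        assert evaluate(forest, test).accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(6)
        n = 400
        sset = matrix_set(rng.normal(size=(n, 10)), ["a", "b"] * (n // 2))
        train, test = split_train_test(sset, 0.8, seed=1)
        forest = fit_forest(train, ForestParams(num_trees=100, seed=1))
        acc = evaluate(forest, test).accuracy
        lo, hi = stats.binom.interval(0.99, test.n, 0.5)
        assert lo / test.n <= acc <= hi / test.n

    def test_deterministic_fit(self):
        rng = np.random.default_rng(7)
        sset = matrix_set(rng.normal(size=(40, 8)), ["a", "b"] * 20)
        train, _ = split_train_test(sset, 0.8, seed=2)
        params = ForestParams(num_trees=15, seed=42)
        f1 = fit_forest(train, params)
        f2 = fit_forest(train, params)
        np.testing.assert_array_equal(
            surrogate_minimal_depth(f1), surrogate_minimal_depth(f2)
        )
        for t1, t2 in zip(f1.trees, f2.trees):
            assert len(t1.nodes) == len(t2.nodes)
            for n1, n2 in zip(t1.nodes, t2.nodes):
                assert (n1.primary_var, n1.depth) == (n2.primary_var, n2.depth)
                assert [s.var for s in n1.surrogates] == [s.var for s in n2.surrogates]


def hand_built_forest(p=6):
    """Two small trees with fixed surrogate lists for enumeration checks."""
    tree1 = SurrogateTree(
        nodes=[
            SplitNode(0, 0.5, 0, 0.5, [Surrogate(1, 0.4, False, 0.9)]),
            SplitNode(2, 1.0, 1, 0.4, [Surrogate(3, 0.2, True, 0.6)]),
            SplitNode(0, 0.2, 1, 0.6, [Surrogate(4, 0.1, False, 0.3)]),
        ],
        max_depth=2,
    )
    tree2 = SurrogateTree(
        nodes=[
            SplitNode(2, 0.8, 0, 0.3, [Surrogate(0, 0.7, False, 0.8)]),
            SplitNode(1, 0.1, 1, 0.5, []),
        ],
        max_depth=2,
    )
    params = ForestParams(num_trees=2, mtry=2, s=2, p=p)
    return SurrogateForest([tree1, tree2], params, np.array(["a", "b"]))


def enumerate_smd(forest):
    """Naive oracle: scan every node of every tree."""
    p = forest.params.p
    out = np.zeros(p)
    for tree in forest.trees:
        depths = {}
        for node in tree.nodes:
            for var in [node.primary_var] + [s.var for s in node.surrogates]:
                depths[var] = min(depths.get(var, np.inf), node.depth)
        out += np.array(
            [depths.get(v, tree.max_depth + 1) for v in range(p)], dtype=float
        )
    return out / len(forest.trees)


def enumerate_maa(forest, i, j):
    if i == j:
        return 1.0
    values = []
    for tree in forest.trees:
        for node in tree.nodes:
            if node.primary_var == i:
                stored = {s.var: s.agreement for s in node.surrogates}
                values.append(stored.get(j, 0.0))
    return float(np.mean(values)) if values else 0.0


class TestSmd:
    def test_hand_built_matches_enumeration_exactly(self):
        forest = hand_built_forest()
        np.testing.assert_array_equal(surrogate_minimal_depth(forest), enumerate_smd(forest))

    def test_root_primary_everywhere_gives_zero(self):
        nodes = [SplitNode(3, 0.0, 0, 0.5, [])]
        trees = [SurrogateTree([SplitNode(3, 0.0, 0, 0.5, [])], 1) for _ in range(4)]
        params = ForestParams(num_trees=4, mtry=1, s=1, p=5)
        forest = SurrogateForest(trees, params, np.array(["a", "b"]))
        assert surrogate_minimal_depth(forest)[3] == 0.0

    def test_absent_variable_penalty(self):
        trees = [
            SurrogateTree([SplitNode(0, 0.0, 0, 0.5, [])], 3),
            SurrogateTree([SplitNode(1, 0.0, 0, 0.5, [])], 3),
        ]
        params = ForestParams(num_trees=2, mtry=1, s=1, p=4)
        forest = SurrogateForest(trees, params, np.array(["a", "b"]))
        assert surrogate_minimal_depth(forest)[3] == 4.0

    def test_smd_range_on_fitted_forest(self):
        rng = np.random.default_rng(8)
        sset = matrix_set(rng.normal(size=(60, 10)), ["a", "b"] * 30)
        forest = fit_forest(sset, ForestParams(num_trees=20, seed=3))
        smd = surrogate_minimal_depth(forest)
        max_penalty = max(t.max_depth + 1 for t in forest.trees)
        assert np.all(smd >= 0) and np.all(smd <= max_penalty)


class TestMaa:
    def test_hand_built_matches_enumeration(self):
        forest = hand_built_forest()
        for i in range(6):
            for j in range(6):
                assert mean_adjusted_agreement(forest, i, j) == pytest.approx(
                    enumerate_maa(forest, i, j)
                )

    def test_self_relation_is_one_and_never_primary_is_zero(self):
        forest = hand_built_forest()
        assert mean_adjusted_agreement(forest, 5, 5) == 1.0
        assert mean_adjusted_agreement(forest, 5, 0) == 0.0

    def test_duplicate_column_perfect_relation_in_fitted_forest(self):
        rng = np.random.default_rng(9)
        n = 80
        labels = ["a", "b"] * (n // 2)
        base = np.where(np.array(labels) == "a", -1.0, 1.0) + rng.normal(0, 0.5, n)
        matrix = np.column_stack([base, base, rng.normal(size=(n, 3))])
        forest = fit_forest(
            matrix_set(matrix, labels), ForestParams(num_trees=10, mtry=5, seed=4)
        )
        for i, j in ((0, 1), (1, 0)):
            if any(node.primary_var == i for t in forest.trees for node in t.nodes):
                assert mean_adjusted_agreement(forest, i, j) == 1.0

    def test_matrix_entries_in_unit_interval(self):
        forest = hand_built_forest()
        rel = maa_matrix(forest, [0, 2])
        assert rel.maa.shape == (2, 6)
        assert np.all(rel.maa >= 0) and np.all(rel.maa <= 1)
        assert rel.maa[0, 0] == 1.0 and rel.maa[1, 2] == 1.0


class TestRepresentatives:
    def test_single_selected_variable(self):
        assert pick_representatives(np.array([4]), np.arange(10.0)) == [4]

    def test_contiguous_group_argmin(self):
        smd = np.full(20, 9.0)
        smd[[10, 11, 12, 13]] = [3.0, 2.0, 1.0, 2.5]
        assert pick_representatives(np.array([10, 11, 12, 13]), smd) == [12]

    def test_tie_broken_toward_lower_wavenumber(self):
        smd = np.full(10, 9.0)
        smd[[3, 4]] = 1.0
        assert pick_representatives(np.array([3, 4]), smd) == [3]

    def test_two_groups_match_brute_force(self):
        rng = np.random.default_rng(10)
        smd = rng.uniform(1, 5, 50)
        selected = np.array([5, 6, 7, 30, 31])
        reps = pick_representatives(selected, smd, gap=2)
        # brute-force grouping oracle
        groups, current = [], [selected[0]]
        for v in selected[1:]:
            if v - current[-1] <= 2:
                current.append(v)
            else:
                groups.append(current)
                current = [v]
        groups.append(current)
        want = [g[int(np.argmin(smd[g]))] for g in groups]
        assert reps == want

    def test_empty_selection_rejected(self):
        with pytest.raises(SelectionError):
            pick_representatives(np.zeros(5, dtype=bool), np.zeros(5))


class TestThreshold:
    def test_threshold_strictly_positive(self):
        rng = np.random.default_rng(11)
        sset = matrix_set(rng.normal(size=(40, 6)), ["a", "b"] * 20)
        thr = smd_threshold(sset, ForestParams(num_trees=25, seed=5), n_null=2, seed=6)
        assert thr > 0.0

    def test_dominant_variable_selected(self):
        hits = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            n = 200
            labels = ["a", "b"] * (n // 2)
            matrix = rng.normal(size=(n, 20))
            matrix[:, 7] += np.where(np.array(labels) == "a", 0.0, 2.0)
            sset = matrix_set(matrix, labels)
            train, _ = split_train_test(sset, 0.8, seed=rep)
            params = ForestParams(num_trees=100, seed=rep)
            forest = fit_forest(train, params)
            smd = surrogate_minimal_depth(forest)
            thr = smd_threshold(train, params, n_null=4, seed=200 + rep)
            if (smd < thr)[7]:
                hits += 1
        assert hits >= 4
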