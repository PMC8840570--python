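"""Ranking, forward-stepwise selection, pool ordering and the hierarchy."""

import numpy as np
import pytest

from glcmtex import (
    ClassifierConfig,
    FeatureTable,
    build_pool,
    evaluate_feature_set,
    fsfs,
    hierarchical_integrate,
    make_scheme,
    mghm_select,
    rank_by_rf_importance,
    roc_auc,
    split_group,
)
from glcmtex.selection import GroupSplit
from conftest import simple_table


CFG = ClassifierConfig(seed=0)


@pytest.fixture
def scheme_small():
    labels = np.tile([0, 1], 20)
    return make_scheme(labels, n_repeats=5, seed=42)


class TestRanking:
    def test_label_copy_ranked_first(self, rng):
        n = 40
        y = np.tile([0, 1], n // 2)
        X = rng.standard_normal((n, 5))
        X[:, 3] = y  # exact copy of the label
        table = FeatureTable(X, y, [f"f{i}" for i in range(5)], np.ones(5, int))
        ranked = rank_by_rf_importance(table, np.arange(5), n_trees=100, seed=0)
        assert ranked[0] == 3

    def test_determinism(self, rng):
        table = simple_table(rng)
        a = rank_by_rf_importance(table, np.arange(8), n_trees=200, seed=7)
        b = rank_by_rf_importance(table, np.arange(8), n_trees=200, seed=7)
        assert np.array_equal(a, b)

    def test_matches_forest_impurity_recomputation(self, rng):
        """Ordering agrees with importances re-derived from the fitted forest."""
        from sklearn.ensemble import RandomForestClassifier

        table = simple_table(rng, n=30, n_noise=1, n_informative=2)
        rf = RandomForestClassifier(n_estimators=50, criterion="gini", random_state=3)
        rf.fit(table.matrix[:, :3], table.labels)
        # recompute mean normalized impurity decrease from each tree's structure
        agg = np.zeros(3)
        for est in rf.estimators_:
            t = est.tree_
            imp = np.zeros(3)
            for node in range(t.node_count):
                if t.children_left[node] == -1:
                    continue
                l, r = t.children_left[node], t.children_right[node]
                gain = (
                    t.weighted_n_node_samples[node] * t.impurity[node]
                    - t.weighted_n_node_samples[l] * t.impurity[l]
                    - t.weighted_n_node_samples[r] * t.impurity[r]
                )
                imp[t.feature[node]] += gain
            imp /= t.weighted_n_node_samples[0]
            if imp.sum() > 0:
                imp /= imp.sum()
            agg += imp
        expected = np.argsort(-(agg / 50), kind="stable")
        ranked = rank_by_rf_importance(table, np.arange(3), n_trees=50, seed=3)
        assert np.array_equal(ranked, expected)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_by_rf_importance(simple_table(rng), np.array([], int))


class TestEvaluateFeatureSet:
    def test_label_feature_perfect_auc(self, scheme_small):
        y = np.tile([0, 1], 20)
        X = np.column_stack([y.astype(float), np.zeros(40)])
        table = FeatureTable(X, y, ["lab", "zero"], np.ones(2, int))
        mean, std = evaluate_feature_set(table, np.array([0]), CFG, scheme_small)
        assert mean == 1.0 and std == 0.0

    def test_noise_feature_near_half(self):
        rng = np.random.default_rng(5)
        y = np.tile([0, 1], 30)
        X = rng.standard_normal((60, 1))
        table = FeatureTable(X, y, ["noise"], np.ones(1, int))
        scheme = make_scheme(y, n_repeats=100, seed=6)
        mean, _ = evaluate_feature_set(table, np.array([0]), CFG, scheme)
        assert 0.4 < mean < 0.6

    def test_matches_manual_single_split(self, rng):
        """One fixed split equals a hand-run SVM train/score/AUC computation."""
        from glcmtex.evalstats import SplitScheme

        table = simple_table(rng, n=20, n_noise=2, n_informative=2)
        train = np.arange(10)
        test = np.arange(10, 20)
        scheme = SplitScheme(kind="two-fold", splits=[(train, test)])
        subset = np.array([0, 1, 2])
        mean, std = evaluate_feature_set(table, subset, CFG, scheme)
        clf = CFG.make(3)
        clf.fit(table.matrix[np.ix_(train, subset)], table.labels[train])
        scores = clf.decision_function(table.matrix[np.ix_(test, subset)])
        assert mean == roc_auc(scores, table.labels[test]) and std == 0.0


def greedy_reference(table, baseline, ranked, cfg, scheme):
    """Independent step-by-step re-simulation of the greedy pass."""
    current = list(baseline)
    best = (
        evaluate_feature_set(table, np.asarray(current), cfg, scheme)[0]
        if current
        else -np.inf
    )
    for c in ranked:
        auc = evaluate_feature_set(table, np.asarray(current + [c]), cfg, scheme)[0]
        if auc > best:
            current.append(c)
            best = auc
    return current, best


class TestFSFS:
    def test_duplicates_of_baseline_never_kept(self, rng, scheme_small):
        y = np.tile([0, 1], 20)
        x = rng.standard_normal(40) + 1.2 * y
        X = np.column_stack([x, x, x])
        table = FeatureTable(X, y, ["a", "b", "c"], np.ones(3, int))
        res = fsfs(table, np.array([0]), np.array([1, 2]), CFG, scheme_small)
        assert res.accepted.size == 0
        assert np.array_equal(res.selected, [0])

    def test_label_candidate_kept_from_empty_baseline(self, scheme_small):
        y = np.tile([0, 1], 20)
        X = y.astype(float)[:, None]
        table = FeatureTable(X, y, ["lab"], np.ones(1, int))
        res = fsfs(table, np.array([], int), np.array([0]), CFG, scheme_small)
        assert np.array_equal(res.selected, [0])
        assert res.final_auc == 1.0

    def test_empty_candidates_return_baseline(self, rng, scheme_small):
        table = simple_table(rng)
        res = fsfs(table, np.array([0, 1]), np.array([], int), CFG, scheme_small)
        assert np.array_equal(res.selected, [0, 1])

    def test_matches_step_by_step_greedy_oracle(self, rng, scheme_small):
        table = simple_table(rng, n=40, n_noise=3, n_informative=2, delta=1.0)
        ranked = rank_by_rf_importance(table, np.arange(5), n_trees=100, seed=1)
        res = fsfs(table, np.array([], int), ranked, CFG, scheme_small)
        expected, best = greedy_reference(table, [], ranked, CFG, scheme_small)
        assert list(res.selected) == expected
        assert np.isclose(res.final_auc, best)

    def test_trace_strictly_increasing(self, rng, scheme_small):
        table = simple_table(rng, n=40, n_noise=6, n_informative=2, delta=0.8)
        ranked = rank_by_rf_importance(table, np.arange(8), n_trees=100, seed=2)
        res = fsfs(table, np.array([], int), ranked, CFG, scheme_small)
        assert all(b > a for a, b in zip(res.auc_trace, res.auc_trace[1:]))


class TestSplitGroup:
    def test_partition_reconstitutes_group(self, rng, scheme_small):
        table = simple_table(rng, groups=[1] * 4 + [2] * 4)
        gs = split_group(table, 1, CFG, scheme_small, n_trees=100)
        union = np.union1d(gs.baseline_idx, gs.complement_idx)
        assert np.array_equal(union, table.group_indices(1))
        assert np.intersect1d(gs.baseline_idx, gs.complement_idx).size == 0

    def test_identical_columns_give_single_feature_baseline(self, rng, scheme_small):
        y = np.tile([0, 1], 20)
        x = rng.standard_normal(40) + y
        X = np.column_stack([x] * 4)
        table = FeatureTable(X, y, list("abcd"), np.ones(4, int))
        gs = split_group(table, 1, CFG, scheme_small, n_trees=100)
        assert gs.baseline_idx.size == 1


def _mk_split(gid, n_base, n_comp, group_auc, baseline_auc, start=0):
    return GroupSplit(
        group_id=gid,
        baseline_idx=np.arange(start, start + n_base),
        complement_idx=np.arange(start + n_base, start + n_base + n_comp),
        group_auc=group_auc,
        group_auc_std=0.0,
        baseline_auc=baseline_auc,
        baseline_auc_std=0.0,
    )


class TestBuildPool:
    def test_reference_ordering(self):
        """Group AUCs 0.854/0.875/0.892 put group 3's baseline first, then
        whole groups 2 and 1, then group 3's complement."""
        splits = {
            1: _mk_split(1, 65, 19, 0.854, 0.854, start=0),
            2: _mk_split(2, 3, 165, 0.875, 0.875, start=84),
            3: _mk_split(3, 6, 106, 0.892, 0.892, start=252),
        }
        pool = build_pool(splits)
        assert [e.source for e in pool.entries] == ["D3b", "D2", "D1", "D3c"]
        assert len(pool) == 4

    def test_tie_break_deterministic(self):
        splits = {
            1: _mk_split(1, 2, 2, 0.8, 0.7, start=0),
            2: _mk_split(2, 2, 6, 0.8, 0.9, start=4),
            3: _mk_split(3, 2, 2, 0.8, 0.7, start=12),
        }
        a = build_pool(splits)
        b = build_pool(dict(reversed(list(splits.items()))))
        assert [e.source for e in a.entries] == [e.source for e in b.entries]
        # best baseline is group 2; groups 1 and 3 tie on AUC -> larger first
        assert a.entries[0].source == "D2b"
        assert a.entries[1].source == "D1"

    def test_pool_length_is_groups_plus_one(self, rng):
        for k in (2, 3, 4):
            splits = {
                g: _mk_split(g, 2, 3, float(rng.random()), float(rng.random()),
                             start=5 * g)
                for g in range(1, k + 1)
            }
            assert len(build_pool(splits)) == k + 1


class TestHierarchy:
    def test_three_groups_give_four_levels(self, rng):
        table = simple_table(
            rng, n=40, n_noise=6, n_informative=3,
            groups=[1, 2, 3] * 3,
        )
        scheme = make_scheme(table.labels, n_repeats=3, seed=0)
        result, _ = mghm_select(table, CFG, scheme, n_trees=100)
        assert len(result.levels) == 4
        assert result.pool_order[0].endswith("b")
        assert result.pool_order[-1].endswith("c")

    def test_noise_candidates_leave_baseline_unchanged(self, rng):
        y = np.tile([0, 1], 20)
        lab = y.astype(float) + 0.01 * rng.standard_normal(40)
        X = np.column_stack([lab] + [rng.standard_normal(40) for _ in range(5)])
        table = FeatureTable(X, y, [f"f{i}" for i in range(6)],
                             np.array([1, 1, 2, 2, 3, 3]))
        scheme = make_scheme(y, n_repeats=3, seed=1)
        result, _ = mghm_select(table, CFG, scheme, n_trees=100)
        aucs = [l.auc_mean for l in result.levels]
        assert aucs[0] == 1.0 and all(a == 1.0 for a in aucs)
        assert 0 in result.selected

    @pytest.mark.parametrize("seed", range(5))
    def test_per_level_auc_monotone_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = simple_table(
            rng, n=40, n_noise=7, n_informative=2, delta=0.7,
            groups=[1, 1, 1, 2, 2, 2, 3, 3, 3],
        )
        scheme = make_scheme(table.labels, n_repeats=3, seed=seed)
        result, _ = mghm_select(table, CFG, scheme, n_trees=100, seed=seed)
        aucs = [l.auc_mean for l in result.levels]
        assert all(b >= a for a, b in zip(aucs, aucs[1:]))
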