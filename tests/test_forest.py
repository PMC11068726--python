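"""Random survival forest: the log-rank split against a hand-computed
closed form, tree growth, proximity accounting, importance scores, Ward
clustering of the proximity and subgroup-count selection."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test
from sklearn.metrics import adjusted_rand_score

from consica import forest, synthetic
from consica.containers import MixingMatrix, SurvivalTable
from consica.forest import ProximityMatrix


def _surv(times, events):
    return SurvivalTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(times))],
                "time": times,
                "event": events,
            }
        )
    )


def _mix(values, ids=None):
    v = np.atleast_2d(np.asarray(values, float))
    ids = ids or [f"TC{i}" for i in range(v.shape[0])]
    return MixingMatrix(ids, [f"S{i}" for i in range(v.shape[1])], v)


class TestLogrankSplit:
    def test_four_sample_closed_form(self):
        # times {1,2,3,4}, all events, group 1 = {t=1, t=2} (low values).
        # Textbook two-group log-rank with d=1 at each event time:
        #   t=1: n=4, n1=2 -> E1 += 2/4;  V += 1*(4-1)/(4-1) * 2*2/16 = 1/4
        #   t=2: n=3, n1=1 -> E1 += 1/3;  V += 1*2/2 * 1*2/9 = 2/9
        #   t=3: n=2, n1=0;  t=4: n=1 -> no contribution
        # O1 = 2, E1 = 5/6, V = 17/36 -> chi2 = (7/6)^2/(17/36) = 49/17
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        values = np.array([0.0, 0.0, 1.0, 1.0])
        expected = 49 / 17
        result = forest.logrank_split(
            values, _surv(times, events), min_node_size=2, min_node_events=1
        )
        assert result is not None
        cut, stat = result
        assert cut == pytest.approx(0.5)
        assert stat == pytest.approx(expected, rel=1e-12)
        # cross-check against lifelines on the same partition
        lr = logrank_test(times[:2], times[2:], events[:2], events[2:])
        assert stat == pytest.approx(lr.test_statistic, rel=1e-12)

    def test_identical_curves_no_split(self):
        # both prospective children see the same survival experience
        times = np.tile([1.0, 2.0, 3.0, 4.0], 2)
        events = np.ones(8, int)
        values = np.repeat([0.0, 1.0], 4)
        times = np.array([1, 2, 3, 4, 1, 2, 3, 4.0])
        result = forest.logrank_split(
            values, _surv(times, events), min_node_size=2, min_node_events=1
        )
        assert result is None or result[1] == pytest.approx(0.0, abs=1e-12)

    def test_small_node_guard(self):
        result = forest.logrank_split(
            np.arange(10.0),
            _surv(np.arange(1.0, 11), np.ones(10, int)),
            min_node_size=6,
            min_node_events=1,
        )
        assert result is None

    def test_constant_values_no_split(self):
        result = forest.logrank_split(
            np.ones(40),
            _surv(np.arange(1.0, 41), np.ones(40, int)),
            min_node_size=5,
            min_node_events=2,
        )
        assert result is None


class TestGrowTree:
    def test_perfect_separator_wins_root(self):
        rng = np.random.default_rng(0)
        n = 120
        g = np.repeat([0.0, 1.0], n // 2)
        A = _mix(np.vstack([rng.normal(size=n), g, rng.normal(size=n)]),
                 ["noise1", "sep", "noise2"])
        surv = synthetic.generate_survival(
            _mix(g, ["g"]), [2.5], 0.05, 0.001, seed=1
        )
        tree = forest.grow_tree(
            A, surv, ["noise1", "sep", "noise2"], min_node_size=10,
            min_node_events=3,
        )
        assert tree.root.split_tc == "sep"
        assert "sep" in tree.used_tcs

    def test_null_candidates_shallow_tree(self):
        rng = np.random.default_rng(1)
        n = 200
        A = _mix(rng.normal(size=(5, n)))
        surv = synthetic.generate_survival(
            A, np.zeros(5), 0.05, 0.02, seed=2
        )
        # survival independent of candidates: the Bonferroni-corrected
        # split threshold keeps most trees single-node
        depths = []
        for seed in range(10):
            cand = [f"TC{i}" for i in range(5)]
            tree = forest.grow_tree(A, surv, cand)
            depths.append(len(set(tree.terminal_labels)))
        assert np.mean(depths) < 2.0

    def test_deterministic_given_data(self):
        rng = np.random.default_rng(2)
        A = _mix(rng.normal(size=(5, 100)))
        surv = synthetic.generate_survival(A, [1, 0, 0, 0, 0.0], 0.05, 0.02, seed=3)
        t1 = forest.grow_tree(A, surv, list(A.component_ids))
        t2 = forest.grow_tree(A, surv, list(A.component_ids))
        np.testing.assert_array_equal(t1.terminal_labels, t2.terminal_labels)


class TestForestAndProximity:
    def test_single_terminal_tree_proximity_all_ones(self):
        rng = np.random.default_rng(3)
        A = _mix(rng.normal(size=(5, 60)))
        surv = synthetic.generate_survival(A, np.zeros(5), 0.05, 0.02, seed=4)
        fst = forest.build_forest(
            A, surv, n_trees=2, tcs_per_tree=5, split_alpha=1e-12, seed=5
        )
        assert (fst.proximity_counts == 2).all()

    def test_diagonal_equals_n_trees_and_symmetry(self):
        rng = np.random.default_rng(4)
        A = _mix(rng.normal(size=(6, 80)))
        surv = synthetic.generate_survival(
            A, [1.5, 0, 0, 0, 0, 0.0], 0.05, 0.02, seed=6
        )
        fst = forest.build_forest(A, surv, n_trees=25, tcs_per_tree=5, seed=7)
        P = forest.final_proximity(fst)
        assert (np.diag(P.counts) == 25).all()
        assert (P.counts == P.counts.T).all()
        assert P.counts.max() <= 25

    def test_too_few_tcs_errors(self):
        A = _mix(np.random.default_rng(5).normal(size=(3, 40)))
        surv = synthetic.generate_survival(A, np.zeros(3), 0.05, 0.02, seed=8)
        with pytest.raises(ValueError, match="TCs"):
            forest.build_forest(A, surv, n_trees=5, tcs_per_tree=5)

    def test_importance_definitional_bounds(self):
        rng = np.random.default_rng(6)
        n = 300
        g = (rng.random(n) > 0.5).astype(float)
        A = _mix(np.vstack([g, rng.normal(size=n)]), ["sep", "noise"])
        surv = synthetic.generate_survival(_mix(g, ["g"]), [2.5], 0.05, 0.001, seed=9)
        fst = forest.build_forest(A, surv, n_trees=30, tcs_per_tree=2, seed=10)
        imp = forest.importance_scores(fst)
        assert imp["sep"] == 1.0  # used in every tree it appears in
        assert 0 <= imp["noise"] <= 1

    def test_planted_subgroups_within_gt_between_proximity(self):
        rng = np.random.default_rng(7)
        k, n = 8, 200
        A = _mix(rng.normal(size=(k, n)))
        truth = (A.activities[2] > np.median(A.activities[2])).astype(float)
        surv = synthetic.generate_survival(_mix(truth, ["g"]), [1.5], 0.02, 0.01, seed=11)
        fst = forest.build_forest(A, surv, n_trees=200, tcs_per_tree=5, seed=12)
        P = fst.proximity_counts.astype(float)
        same = truth[:, None] == truth[None, :]
        iu = np.triu_indices(n, 1)
        within = P[iu][same[iu]].mean()
        between = P[iu][~same[iu]].mean()
        assert within > between


class TestClusterProximity:
    def _block_proximity(self, n1, n2, n_trees=100):
        n = n1 + n2
        counts = np.zeros((n, n), int)
        counts[:n1, :n1] = n_trees
        counts[n1:, n1:] = n_trees
        np.fill_diagonal(counts, n_trees)
        ids = [f"s{i}" for i in range(n)]
        return ProximityMatrix(ids, counts, n_trees)

    def test_perfect_blocks_recovered(self):
        P = self._block_proximity(12, 18)
        labels = forest.cluster_proximity(P, 2)
        truth = np.repeat([0, 1], [12, 18])
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_singletons(self):
        P = self._block_proximity(3, 3)
        labels = forest.cluster_proximity(P, 6)
        assert len(set(labels)) == 6

    def test_k_exceeds_n_errors(self):
        P = self._block_proximity(3, 3)
        with pytest.raises(ValueError):
            forest.cluster_proximity(P, 7)


class TestSelectMaxSubgroups:
    def test_identical_survival_k_star_one(self):
        rng = np.random.default_rng(8)
        n = 60
        counts = np.full((n, n), 50, int)
        P = ProximityMatrix([f"s{i}" for i in range(n)], counts, 50)
        # survival identical in distribution and clusters arbitrary
        surv = _surv(np.tile(np.arange(1.0, 31), 2), np.ones(n, int))
        surv.data["sample_id"] = [f"s{i}" for i in range(n)]
        k, labels, table = forest.select_max_subgroups(P, surv, k_max=4)
        assert k == 1
        assert (labels == 1).all()

    def test_alpha_one_selects_k_max(self):
        rng = np.random.default_rng(9)
        k, n = 6, 120
        A = _mix(rng.normal(size=(k, n)))
        surv = synthetic.generate_survival(A, np.zeros(k), 0.05, 0.02, seed=13)
        fst = forest.build_forest(A, surv, n_trees=40, tcs_per_tree=5,
                                  split_alpha=1.0, seed=14)
        P = forest.final_proximity(fst)
        kstar, _, _ = forest.select_max_subgroups(P, surv, k_max=5, alpha=1.0)
        assert kstar == 5

    def test_two_planted_hazard_groups_detected(self):
        rng = np.random.default_rng(10)
        k, n = 8, 240
        A = _mix(rng.normal(size=(k, n)))
        truth = (A.activities[0] > np.median(A.activities[0])).astype(float)
        surv = synthetic.generate_survival(_mix(truth, ["g"]), [1.8], 0.02, 0.01, seed=15)
        fst = forest.build_forest(A, surv, n_trees=300, tcs_per_tree=4, seed=16)
        P = forest.final_proximity(fst)
        kstar, labels, _ = forest.select_max_subgroups(P, surv)
        assert kstar >= 2
        two = forest.cluster_proximity(P, 2)
        assert adjusted_rand_score(truth, two) >= 0.8


class TestCompareProximity:
    def test_self_correlation_one(self):
        rng = np.random.default_rng(11)
        C = rng.integers(0, 50, size=(20, 20))
        C = C + C.T
        np.fill_diagonal(C, 100)
        P = ProximityMatrix([f"s{i}" for i in range(20)], C, 100)
        assert forest.compare_proximity(P, P) == pytest.approx(1.0)

    def test_shuffled_near_zero(self):
        rng = np.random.default_rng(12)
        n = 60
        C = rng.integers(0, 50, size=(n, n))
        C = C + C.T
        np.fill_diagonal(C, 100)
        ids = [f"s{i}" for i in range(n)]
        P1 = ProximityMatrix(ids, C, 100)
        perm = rng.permutation(n)
        C2 = C[np.ix_(perm, perm)]
        np.fill_diagonal(C2, 100)
        P2 = ProximityMatrix(ids, C2, 100)
        assert abs(forest.compare_proximity(P1, P2)) < 0.15

    def test_mismatched_samples_error(self):
        C = np.full((3, 3), 5)
        P1 = ProximityMatrix(["a", "b", "c"], C, 5)
        P2 = ProximityMatrix(["a", "b", "d"], C, 5)
        with pytest.raises(ValueError):
            forest.compare_proximity(P1, P2)
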