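"""Evaluation metrics against independent oracles and enumerated examples."""

import itertools
from collections import deque

import numpy as np
import pytest
from sklearn.metrics import roc_curve

from pcnt import (
    GroundTruthGraph,
    WeightedGraph,
    coefficient_correlation,
    evaluate,
    f1_oriented,
    orientation_accuracy,
    regulator_auc,
    regulator_scores,
    shd,
    subsample_ground_truth,
)

from test_graph import all_3node_supports


def truth_from(W: np.ndarray, gene_ids=None) -> GroundTruthGraph:
    labels = (np.asarray(W) != 0).any(axis=1)
    return GroundTruthGraph(W, labels, gene_ids or [])


def graph_edit_distances():
    """All-pairs minimal edit distance (add/delete/reverse) between 3-node
    digraphs, by breadth-first search over the 64-graph space."""
    supports = [tuple((W != 0).ravel()) for W in all_3node_supports()]
    index = {s: k for k, s in enumerate(supports)}
    offdiag = [(i, j) for i in range(3) for j in range(3) if i != j]

    def neighbors(s):
        A = np.array(s).reshape(3, 3)
        for i, j in offdiag:
            B = A.copy()
            if A[i, j]:
                B[i, j] = 0  # delete
                yield tuple(B.ravel())
                if not A[j, i]:
                    C = A.copy()
                    C[i, j], C[j, i] = 0, 1  # reverse
                    yield tuple(C.ravel())
            else:
                B[i, j] = 1  # add
                yield tuple(B.ravel())

    dist = np.full((64, 64), -1, dtype=int)
    for start in range(64):
        dist[start, start] = 0
        queue = deque([supports[start]])
        while queue:
            s = queue.popleft()
            for t in neighbors(s):
                if dist[start, index[t]] < 0:
                    dist[start, index[t]] = dist[start, index[s]] + 1
                    queue.append(t)
    return supports, dist


class TestSHD:
    def test_identical_graphs(self):
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        assert shd(WeightedGraph(W), truth_from(W)) == 0

    def test_empty_prediction_costs_every_true_edge(self):
        W = np.zeros((4, 4))
        W[0, 1], W[0, 2], W[1, 3] = 1, 1, -1
        assert shd(WeightedGraph(np.zeros((4, 4))), truth_from(W)) == 3

    def test_single_reversal_costs_one(self):
        Wt = np.zeros((3, 3))
        Wt[0, 1] = 1.0
        Wp = np.zeros((3, 3))
        Wp[1, 0] = 1.0
        assert shd(WeightedGraph(Wp), truth_from(Wt)) == 1

    def test_matches_breadth_first_edit_search_on_all_3node_pairs(self):
        supports, dist = graph_edit_distances()
        acyclic = {}
        for k, s in enumerate(supports):
            W = np.array(s, dtype=float).reshape(3, 3)
            try:
                acyclic[k] = truth_from(W)
            except ValueError:
                continue  # cyclic supports cannot be ground truths
        for i, sp in enumerate(supports):
            pred = WeightedGraph(np.array(sp, dtype=float).reshape(3, 3))
            for j, truth in acyclic.items():
                assert shd(pred, truth) == dist[i, j]

    def test_gene_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="gene"):
            shd(
                WeightedGraph(np.zeros((2, 2)), ["A", "B"]),
                truth_from(np.zeros((2, 2)), ["A", "C"]),
            )


class TestF1Oriented:
    def test_perfect_prediction(self):
        W = np.zeros((3, 3))
        W[0, 1], W[1, 2] = 1, 1
        assert f1_oriented(WeightedGraph(W), truth_from(W)) == (1.0, 1.0, 1.0)

    def test_disjoint_edge_sets(self):
        Wt = np.zeros((3, 3))
        Wt[0, 1] = 1
        Wp = np.zeros((3, 3))
        Wp[1, 2] = 1
        assert f1_oriented(WeightedGraph(Wp), truth_from(Wt)) == (0.0, 0.0, 0.0)

    def test_enumerated_partial_overlap(self):
        # truth 4 edges, prediction 5 edges, 3 shared
        Wt = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 4)]:
            Wt[i, j] = 1.0
        Wp = np.zeros((5, 5))
        for i, j in [(0, 1), (0, 2), (1, 3), (3, 4), (4, 0)]:
            Wp[i, j] = 1.0
        precision, recall, f1 = f1_oriented(WeightedGraph(Wp), truth_from(Wt))
        assert precision == pytest.approx(0.6)
        assert recall == pytest.approx(0.75)
        assert f1 == pytest.approx(2 / 3)

    def test_invariant_under_simultaneous_relabeling(self):
        rng = np.random.default_rng(0)
        Wt = np.triu(rng.normal(size=(5, 5)) * (rng.random((5, 5)) < 0.4), 1)
        Wp = np.triu(rng.normal(size=(5, 5)) * (rng.random((5, 5)) < 0.4), 1)
        base = f1_oriented(WeightedGraph(Wp), truth_from(Wt))
        perm = rng.permutation(5)
        P = np.ix_(perm, perm)
        relabeled = f1_oriented(WeightedGraph(Wp[P]), truth_from(Wt[P]))
        assert base == relabeled


class TestOrientationAccuracy:
    def test_perfect_prediction_scores_one(self):
        W = np.zeros((3, 3))
        W[0, 1], W[1, 2] = 1, -1
        assert orientation_accuracy(WeightedGraph(W), truth_from(W)) == 1.0

    def test_all_reversed_scores_zero(self):
        Wt = np.zeros((3, 3))
        Wt[0, 1], Wt[1, 2] = 1, 1
        assert orientation_accuracy(WeightedGraph(Wt.T.copy()), truth_from(Wt)) == 0.0

    def test_two_of_three_shared_adjacencies_correct(self):
        Wt = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            Wt[i, j] = 1.0
        Wp = np.zeros((4, 4))
        Wp[0, 1], Wp[1, 2], Wp[3, 2] = 1, 1, 1  # last one reversed
        assert orientation_accuracy(WeightedGraph(Wp), truth_from(Wt)) == pytest.approx(2 / 3)

    def test_bidirected_prediction_counts_as_incorrect(self):
        Wt = np.zeros((2, 2))
        Wt[0, 1] = 1.0
        Wp = np.array([[0, 1.0], [1.0, 0]])
        assert orientation_accuracy(WeightedGraph(Wp), truth_from(Wt)) == 0.0

    def test_undefined_without_shared_adjacency(self):
        Wt = np.zeros((3, 3))
        Wt[0, 1] = 1.0
        assert np.isnan(orientation_accuracy(WeightedGraph(np.zeros((3, 3))), truth_from(Wt)))

    def test_unaffected_by_false_positives_on_pairs_absent_from_truth(self):
        rng = np.random.default_rng(1)
        Wt = np.triu(rng.normal(size=(6, 6)) * (rng.random((6, 6)) < 0.4), 1)
        truth = truth_from(Wt)
        Wp = Wt.copy()
        Wp[4, 1] = 0.0  # drop one true edge to make it non-trivial
        base = orientation_accuracy(WeightedGraph(Wp), truth)
        Wfp = Wp.copy()
        for i, j in [(5, 0), (3, 0), (5, 2)]:
            if Wt[i, j] == 0 and Wt[j, i] == 0:
                Wfp[i, j] = 9.9
        assert orientation_accuracy(WeightedGraph(Wfp), truth) == base


class TestRegulatorPrediction:
    def test_zero_graph_scores_all_zero(self):
        assert not regulator_scores(WeightedGraph(np.zeros((4, 4)))).any()

    def test_single_negative_edge_counts_absolute_weight(self):
        W = np.zeros((3, 3))
        W[0, 1] = -2.0
        s = regulator_scores(WeightedGraph(W))
        assert s[0] == 2.0 and s[1] == 0.0 and s[2] == 0.0

    def test_scores_equal_loop_computed_row_sums(self):
        rng = np.random.default_rng(2)
        W = rng.normal(size=(5, 5))
        np.fill_diagonal(W, 0)
        s = regulator_scores(WeightedGraph(W))
        for i in range(5):
            assert s[i] == pytest.approx(sum(abs(W[i, j]) for j in range(5)))

    def test_perfect_separation_gives_auroc_one(self):
        auroc, auprc = regulator_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert auroc == 1.0 and auprc == 1.0

    def test_constant_scores_give_half_auroc(self):
        auroc, _ = regulator_auc(np.ones(6), np.array([1, 0, 1, 0, 0, 0]))
        assert auroc == 0.5

    def test_hand_computed_u_statistic(self):
        # pairs: (0.9 vs 0.8) correct, (0.3 vs 0.8) incorrect -> U/nm = 1/2
        auroc, _ = regulator_auc(np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1]))
        assert auroc == 0.5

    def test_single_class_labels_flagged_undefined(self):
        auroc, auprc = regulator_auc(np.array([0.5, 0.1]), np.array([1, 1]))
        assert np.isnan(auroc) and np.isnan(auprc)

    def test_rank_formula_agrees_with_trapezoidal_integration(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = rng.integers(6, 30)
            scores = np.round(rng.random(n), 2)  # ties included
            labels = rng.integers(0, 2, n)
            if labels.all() or not labels.any():
                continue
            auroc, _ = regulator_auc(scores, labels)
            # oracle 1: normalized Mann-Whitney U with half-ties
            pos, neg = scores[labels == 1], scores[labels == 0]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc == pytest.approx(u / (len(pos) * len(neg)))
            # oracle 2: trapezoidal integration of the ROC curve
            fpr, tpr, _ = roc_curve(labels, scores)
            assert auroc == pytest.approx(np.trapezoid(tpr, fpr))


class TestCoefficientCorrelation:
    def _pair(self, w_pred, w_true):
        d = len(w_pred) + 1
        Wt = np.zeros((d, d))
        Wp = np.zeros((d, d))
        for k, (a, b) in enumerate(zip(w_pred, w_true)):
            Wp[0, k + 1] = a
            Wt[0, k + 1] = b
        return WeightedGraph(Wp), truth_from(Wt)

    def test_identical_weights_give_one(self):
        p, t = self._pair([1, 2, 3], [1, 2, 3])
        assert coefficient_correlation(p, t) == pytest.approx(1.0)

    def test_negated_weights_give_minus_one(self):
        p, t = self._pair([1, 2, 3], [-1, -2, -3])
        assert coefficient_correlation(p, t) == pytest.approx(-1.0)

    def test_exact_linear_scaling_gives_one(self):
        p, t = self._pair([1, 2, 3, 4], [2, 4, 6, 8])
        assert coefficient_correlation(p, t) == pytest.approx(1.0)

    def test_undefined_below_three_true_positives(self):
        p, t = self._pair([1, 2], [1, 2])
        assert np.isnan(coefficient_correlation(p, t))

    def test_only_orientation_matched_edges_counted(self):
        Wt = np.zeros((3, 3))
        Wt[0, 1], Wt[0, 2] = 1.0, 2.0
        Wp = np.zeros((3, 3))
        Wp[1, 0], Wp[0, 2] = 1.0, 2.0  # first edge reversed: not a TP
        from pcnt.metrics import true_positive_weights

        w_pred, w_true = true_positive_weights(WeightedGraph(Wp), truth_from(Wt))
        assert list(w_pred) == [2.0] and list(w_true) == [2.0]


class TestSubsampleGroundTruth:
    def _truth(self, n_reg=6, n_tgt=30, seed=0):
        rng = np.random.default_rng(seed)
        d = n_reg + n_tgt
        W = np.zeros((d, d))
        for i in range(n_reg):
            for j in range(n_reg, d):
                if rng.random() < 0.3:
                    W[i, j] = rng.normal()
        labels = np.zeros(d, dtype=bool)
        labels[:n_reg] = True
        return GroundTruthGraph(W, labels, [f"g{i}" for i in range(d)])

    def test_exact_size_truth_returns_full_graph_every_repeat(self):
        truth = self._truth(n_reg=5, n_tgt=25)
        subs = subsample_ground_truth(truth, n_repeats=4, seed=0)
        for sub in subs:
            assert sorted(sub.gene_ids) == sorted(truth.gene_ids)
            assert sub.W_true.sum() == pytest.approx(truth.W_true.sum())

    def test_induced_subgraph_membership_matches_brute_force(self):
        truth = self._truth()
        for sub in subsample_ground_truth(truth, n_repeats=5, seed=3):
            pos = {g: truth.gene_ids.index(g) for g in sub.gene_ids}
            for a, ga in enumerate(sub.gene_ids):
                for b, gb in enumerate(sub.gene_ids):
                    assert sub.W_true[a, b] == truth.W_true[pos[ga], pos[gb]]

    def test_seeded_determinism(self):
        truth = self._truth()
        a = subsample_ground_truth(truth, n_repeats=3, seed=5)
        b = subsample_ground_truth(truth, n_repeats=3, seed=5)
        c = subsample_ground_truth(truth, n_repeats=3, seed=6)
        assert all(x.gene_ids == y.gene_ids for x, y in zip(a, b))
        assert any(x.gene_ids != y.gene_ids for x, y in zip(a, c))

    def test_insufficient_regulators_rejected(self):
        truth = self._truth(n_reg=3)
        with pytest.raises(ValueError, match="regulators"):
            subsample_ground_truth(truth)


class TestEvaluateBundle:
    def test_report_fields_consistent(self):
        rng = np.random.default_rng(4)
        Wt = np.triu(rng.normal(size=(8, 8)) * (rng.random((8, 8)) < 0.3), 1)
        truth = truth_from(Wt)
        Wp = Wt.copy()
        Wp[Wp != 0] += rng.normal(scale=0.05, size=(Wp != 0).sum())
        report = evaluate(WeightedGraph(Wp), truth)
        assert report.shd == 0
        assert report.f1 == 1.0
        assert report.orientation_accuracy == 1.0
        assert report.n_true_positive_edges == int((Wt != 0).sum())
        p, r = report.precision, report.recall
        assert report.f1 == pytest.approx(2 * p * r / (p + r))
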