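"""Graph-structure and effect-size evaluation metrics.

Structure metrics compare the support of a predicted weighted graph against
a ground-truth causal graph: structural Hamming distance (reversal costs a
single operation), precision/recall/F1 on oriented edges, and orientation
accuracy restricted to adjacencies shared by both graphs (so it is immune to
false-positive edges and to truth incompleteness). Regulator prediction
scores each gene by total absolute outgoing weight and compares against the
binary regulator labels via AUROC/AUPRC. Effect sizes are assessed by the
Pearson correlation of predicted vs true coefficients over true-positive
(orientation-matched) edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import GroundTruthGraph, WeightedGraph


def _check_same_genes(pred: WeightedGraph, truth: GroundTruthGraph) -> None:
    if pred.gene_ids != truth.gene_ids:
        raise ValueError("predicted and truth graphs are over different gene sets")


@dataclass
class EvaluationReport:
    """All metrics for one (prediction, ground truth) pair.

    ``orientation_accuracy`` is NaN when the graphs share no adjacency and
    ``coefficient_correlation`` is NaN with fewer than 3 true-positive edges
    or a constant weight vector; NaN rows are excluded from aggregation.
    """

    shd: int
    precision: float
    recall: float
    f1: float
    orientation_accuracy: float
    regulator_auroc: float
    regulator_auprc: float
    coefficient_correlation: float
    n_true_positive_edges: int
    n_pred_edges: int
    n_truth_edges: int

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def shd(pred: WeightedGraph, truth: GroundTruthGraph) -> int:
    """Structural Hamming distance with unit reversal cost.

    Counted per unordered pair from the edge patterns (none / i->j / j->i /
    both): one operation fixes any single-edge discrepancy or removes one
    arm of a spurious 2-cycle; only none vs both costs two.
    """
    _check_same_genes(pred, truth)
    A = pred.support()
    B = truth.W_true != 0
    d = A.shape[0]
    total = 0
    for i in range(d):
        for j in range(i + 1, d):
            pa = (bool(A[i, j]), bool(A[j, i]))
            pb = (bool(B[i, j]), bool(B[j, i]))
            if pa == pb:
                continue
            na, nb = sum(pa), sum(pb)
            total += 2 if {na, nb} == {0, 2} else 1
    return total


def f1_oriented(
    pred: WeightedGraph, truth: GroundTruthGraph
) -> tuple[float, float, float]:
    """Precision, recall and F1 on directed edges (0/0 conventions -> 0)."""
    _check_same_genes(pred, truth)
    A = pred.support()
    B = truth.W_true != 0
    tp = int((A & B).sum())
    n_pred = int(A.sum())
    n_truth = int(B.sum())
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_truth if n_truth else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def orientation_accuracy(pred: WeightedGraph, truth: GroundTruthGraph) -> float:
    """Direction agreement over adjacencies present in both graphs.

    A pair predicted in both directions counts as incorrectly oriented. NaN
    when no adjacency is shared.
    """
    _check_same_genes(pred, truth)
    A = pred.support()
    B = truth.W_true != 0
    shared = 0
    correct = 0
    d = A.shape[0]
    for i in range(d):
        for j in range(i + 1, d):
            if not ((A[i, j] or A[j, i]) and (B[i, j] or B[j, i])):
                continue
            shared += 1
            if A[i, j] and A[j, i]:
                continue  # bidirected prediction is never correct
            if (A[i, j] == B[i, j]) and (A[j, i] == B[j, i]):
                correct += 1
    return correct / shared if shared else float("nan")


def regulator_scores(pred: WeightedGraph) -> np.ndarray:
    """Per-gene regulatory potential: total absolute outgoing weight."""
    return np.abs(pred.W).sum(axis=1)


def regulator_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """AUROC and AUPRC (average precision) of regulator recovery.

    AUROC is the normalized Mann-Whitney U with ties counted one half; both
    are NaN when the labels are single-class.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        return float("nan"), float("nan")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def true_positive_weights(
    pred: WeightedGraph, truth: GroundTruthGraph
) -> tuple[np.ndarray, np.ndarray]:
    """Paired (predicted, true) weights on orientation-matched shared edges."""
    _check_same_genes(pred, truth)
    mask = pred.support() & (truth.W_true != 0)
    return pred.W[mask], truth.W_true[mask]


def coefficient_correlation(pred: WeightedGraph, truth: GroundTruthGraph) -> float:
    """Pearson r between predicted and true signed effects on true positives.

    NaN with fewer than 3 true-positive edges or a constant vector.
    """
    w_pred, w_true = true_positive_weights(pred, truth)
    if len(w_pred) < 3 or np.ptp(w_pred) == 0 or np.ptp(w_true) == 0:
        return float("nan")
    return float(stats.pearsonr(w_pred, w_true).statistic)


def subsample_ground_truth(
    truth: GroundTruthGraph,
    n_regulators: int = 5,
    n_targets: int = 25,
    n_repeats: int = 20,
    seed: int = 0,
) -> list[GroundTruthGraph]:
    """Induced subgraphs on randomly chosen regulator/target subsets.

    Each repeat draws ``n_regulators`` labelled regulators and ``n_targets``
    non-regulators uniformly without replacement and restricts the graph to
    those genes; connectivity is deliberately not required. Repeats use
    seeds ``seed + r``.
    """
    labels = truth.regulator_labels
    regs = np.nonzero(labels)[0]
    tgts = np.nonzero(~labels)[0]
    if len(regs) < n_regulators:
        raise ValueError(f"need {n_regulators} regulators, graph has {len(regs)}")
    if len(tgts) < n_targets:
        raise ValueError(f"need {n_targets} targets, graph has {len(tgts)}")
    out = []
    for r in range(n_repeats):
        rng = np.random.default_rng((seed + r) % 2**31)
        chosen = np.concatenate(
            [
                np.sort(rng.choice(regs, size=n_regulators, replace=False)),
                np.sort(rng.choice(tgts, size=n_targets, replace=False)),
            ]
        )
        out.append(
            GroundTruthGraph(
                truth.W_true[np.ix_(chosen, chosen)],
                labels[chosen],
                [truth.gene_ids[i] for i in chosen],
            )
        )
    return out


def evaluate(pred: WeightedGraph, truth: GroundTruthGraph) -> EvaluationReport:
    """Bundle all structure, regulator and effect-size metrics."""
    precision, recall, f1 = f1_oriented(pred, truth)
    auroc, auprc = regulator_auc(regulator_scores(pred), truth.regulator_labels)
    w_pred, _ = true_positive_weights(pred, truth)
    return EvaluationReport(
        shd=shd(pred, truth),
        precision=precision,
        recall=recall,
        f1=f1,
        orientation_accuracy=orientation_accuracy(pred, truth),
        regulator_auroc=auroc,
        regulator_auprc=auprc,
        coefficient_correlation=coefficient_correlation(pred, truth),
        n_true_positive_edges=len(w_pred),
        n_pred_edges=int(pred.support().sum()),
        n_truth_edges=int((truth.W_true != 0).sum()),
    )
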