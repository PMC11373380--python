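"""Core graph containers and elementary manipulations.

Orientation convention used throughout the package: ``W[i, j] != 0`` means
gene *i* causally affects gene *j* ("row causes column"), matching the
linear structural equation model ``X = X W + E``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


def _default_gene_ids(d: int) -> list[str]:
    return [f"G{i}" for i in range(d)]


@dataclass
class ExpressionMatrix:
    """Observational expression data: ``n`` samples by ``d`` genes.

    Units are arbitrary; downstream estimators standardize per gene.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D samples x genes array")
        n, d = self.values.shape
        if d < 2:
            raise ValueError(f"need at least 2 genes, got {d}")
        if n < 4:
            raise ValueError(f"need at least 4 samples for a Fisher-z test, got {n}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if not self.gene_ids:
            self.gene_ids = _default_gene_ids(d)
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def standardized(self) -> "ExpressionMatrix":
        """Per-gene zero mean, unit variance copy (constant genes left at 0)."""
        v = self.values - self.values.mean(axis=0, keepdims=True)
        sd = v.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix(v / sd, list(self.gene_ids), list(self.sample_ids))


@dataclass
class CPDAG:
    """Partially directed graph over genes.

    ``amat[i, j] = 1`` is an edge mark at *j* coming from *i*: a directed
    edge i -> j is ``amat[i, j] = 1, amat[j, i] = 0``; an undirected edge
    i - j sets both entries to 1.
    """

    amat: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.amat = np.asarray(self.amat, dtype=int)
        d = _check_square(self.amat)
        if not np.isin(self.amat, (0, 1)).all():
            raise ValueError("CPDAG entries must be 0 or 1")
        if np.diagonal(self.amat).any():
            raise ValueError("CPDAG has a nonzero diagonal")
        if not self.gene_ids:
            self.gene_ids = _default_gene_ids(d)
        elif len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match matrix dimension")

    @property
    def n_genes(self) -> int:
        return self.amat.shape[0]

    def directed_edges(self) -> list[tuple[int, int]]:
        out = []
        for i, j in zip(*np.nonzero(self.amat)):
            if self.amat[j, i] == 0:
                out.append((int(i), int(j)))
        return out

    def undirected_edges(self) -> list[tuple[int, int]]:
        out = []
        for i, j in zip(*np.nonzero(self.amat)):
            if i < j and self.amat[j, i] == 1:
                out.append((int(i), int(j)))
        return out

    def n_edges(self) -> int:
        return len(self.directed_edges()) + len(self.undirected_edges())


@dataclass
class WeightedGraph:
    """Weighted directed graph: ``W[i, j]`` is the signed linear effect of i on j."""

    W: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        d = _check_square(self.W)
        if np.diagonal(self.W).any():
            raise ValueError("weighted graph has a nonzero diagonal")
        if not self.gene_ids:
            self.gene_ids = _default_gene_ids(d)
        elif len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match matrix dimension")

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]

    def support(self) -> np.ndarray:
        return self.W != 0

    def edges(self) -> list[tuple[int, int, float]]:
        return [(int(i), int(j), float(self.W[i, j])) for i, j in zip(*np.nonzero(self.W))]


@dataclass
class ConstraintMask:
    """Boolean edge-permission matrix: ``allowed[i, j]`` iff i -> j may be nonzero."""

    allowed: np.ndarray

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=bool)
        _check_square(self.allowed)
        if np.diagonal(self.allowed).any():
            raise ValueError("constraint mask must forbid self-loops")

    @property
    def n_genes(self) -> int:
        return self.allowed.shape[0]


@dataclass
class GroundTruthGraph:
    """Reference causal graph with regulator labels for evaluation.

    A regulator is any node with at least one outgoing edge; nodes may be
    labelled regulators even without outgoing edges in an induced subgraph.
    """

    W_true: np.ndarray
    regulator_labels: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        d = _check_square(self.W_true)
        self.regulator_labels = np.asarray(self.regulator_labels, dtype=bool)
        if self.regulator_labels.shape != (d,):
            raise ValueError("regulator_labels length does not match matrix dimension")
        if np.diagonal(self.W_true).any():
            raise ValueError("ground truth has a nonzero diagonal")
        if not is_acyclic(WeightedGraph(self.W_true)):
            raise ValueError("ground truth graph contains a cycle")
        has_out = (self.W_true != 0).any(axis=1)
        if (has_out & ~self.regulator_labels).any():
            raise ValueError("node with outgoing edges not labelled as regulator")
        if not self.gene_ids:
            self.gene_ids = _default_gene_ids(d)
        elif len(self.gene_ids) != d:
            raise ValueError("gene_ids length does not match matrix dimension")

    @property
    def n_genes(self) -> int:
        return self.W_true.shape[0]

    def as_weighted_graph(self) -> WeightedGraph:
        return WeightedGraph(self.W_true.copy(), list(self.gene_ids))


def _check_square(a: np.ndarray) -> int:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    return a.shape[0]


def threshold_graph(g: WeightedGraph, w_threshold: float) -> WeightedGraph:
    """Zero out entries with absolute weight below ``w_threshold``."""
    if w_threshold < 0:
        raise ValueError("w_threshold must be non-negative")
    W = g.W.copy()
    W[np.abs(W) < w_threshold] = 0.0
    return WeightedGraph(W, list(g.gene_ids))


def select_top_k_edges(g: WeightedGraph, k: int) -> WeightedGraph:
    """Keep the ``k`` largest-|weight| edges, zeroing the rest.

    Ties at the k-th rank are broken by (row, column) lexicographic order so
    the selection is deterministic. Fewer than ``k`` nonzeros are all kept.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    rows, cols = np.nonzero(g.W)
    order = sorted(
        range(len(rows)),
        key=lambda t: (-abs(g.W[rows[t], cols[t]]), rows[t], cols[t]),
    )
    keep = order[:k]
    W = np.zeros_like(g.W)
    for t in keep:
        W[rows[t], cols[t]] = g.W[rows[t], cols[t]]
    return WeightedGraph(W, list(g.gene_ids))


def is_acyclic(g: WeightedGraph) -> bool:
    """True iff the support of ``W`` has no directed cycle."""
    G = nx.from_numpy_array(g.support().astype(int), create_using=nx.DiGraph)
    return nx.is_directed_acyclic_graph(G)


def break_cycles_by_weight(g: WeightedGraph) -> WeightedGraph:
    """Delete weakest cycle-participating edges until the support is a DAG.

    Repeatedly removes the globally smallest-|weight| edge lying inside a
    strongly connected component (ties broken by row, column), so for a
    2-cycle this keeps the dominant direction. Acyclic inputs are returned
    unchanged (up to a copy).
    """
    W = g.W.copy()
    while True:
        G = nx.from_numpy_array(W != 0, create_using=nx.DiGraph)
        comp_of: dict[int, int] = {}
        for cid, comp in enumerate(nx.strongly_connected_components(G)):
            if len(comp) > 1:
                for v in comp:
                    comp_of[v] = cid
        if not comp_of:
            return WeightedGraph(W, list(g.gene_ids))
        _, i, j = min(
            (abs(W[i, j]), i, int(j))
            for i in comp_of
            for j in np.nonzero(W[i])[0]
            if comp_of.get(int(j), -1) == comp_of[i]
        )
        W[i, j] = 0.0
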