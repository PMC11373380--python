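"""Synthetic ground-truth graphs and linear-SEM expression data.

Biological regulatory networks are sparse and hierarchical: a few regulators
(transcription factors, signalling proteins) each influence many downstream
targets, giving star-like graphs. The generator reproduces that structure —
a small regulator block wired acyclically among itself plus dense
regulator-to-target edges, targets having no outgoing edges — and simulates
observational expression as a linear structural equation model
``X = X W + E`` with independent additive noise, evaluated in topological
order.

What this emulates, and what it does not: the star topology, linear signed
effects and additive noise match the assumed structure of perturbation- and
eQTL-derived regulatory graphs, but single-cell count noise, measurement
batch effects and latent (unmeasured) regulators are not modelled unless
``latent_confounding`` is switched on, which hides a subset of regulator
columns from the returned matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import ExpressionMatrix, GroundTruthGraph, WeightedGraph, is_acyclic


@dataclass
class SimConfig:
    """Generator settings.

    Defaults give a 5-regulator, 25-target star graph with effect magnitudes
    uniform in [0.5, 1.5] (bounded away from zero so edges are detectable at
    n around 1000), random signs, and unit Gaussian noise.
    """

    n_regulators: int = 5
    n_targets: int = 25
    p_edge_reg_to_target: float = 0.2
    p_edge_reg_to_reg: float = 0.1
    weight_magnitude_range: tuple[float, float] = (0.5, 1.5)
    sign_flip_prob: float = 0.5
    noise_sd: float = 1.0
    noise_dist: str = "gaussian"
    n_samples: int = 1000
    seed: int = 0
    coregulation: bool = True
    latent_confounding: bool = False
    n_latent: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_edge_reg_to_target, self.p_edge_reg_to_reg, self.sign_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge/sign probabilities must lie in [0, 1]")
        lo, hi = self.weight_magnitude_range
        if lo > hi or lo < 0:
            raise ValueError("weight_magnitude_range must satisfy 0 <= low <= high")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        if self.noise_dist not in ("gaussian", "gumbel"):
            raise ValueError("noise_dist must be 'gaussian' or 'gumbel'")


def generate_star_dag(cfg: SimConfig) -> GroundTruthGraph:
    """Sample a star-like regulator/target DAG with signed weights.

    Regulator-to-regulator edges follow a fixed topological (index) order so
    the regulator block is upper-triangular, hence acyclic; targets never
    have outgoing edges. Regulator labels mark the regulator block whether
    or not an edge was drawn for it.

    With ``coregulation`` on (the default), a target that drew exactly one
    parent receives a second, randomly chosen regulator parent. Regulatory
    programs overlap in real networks — perturbation-responsive genes tend
    to respond to several of the profiled regulators — and this overlap is
    what makes edge directions identifiable: every regulated target is then
    a collider, so reversing an edge into it would create or destroy a
    v-structure. Without it, single-parent star edges are Markov-equivalent
    to their reversals and no method can orient them from observational
    data.
    """
    rng = np.random.default_rng(cfg.seed % 2**31)
    r, t = cfg.n_regulators, cfg.n_targets
    d = r + t
    W = np.zeros((d, d))
    lo, hi = cfg.weight_magnitude_range

    def draw_weight() -> float:
        mag = rng.uniform(lo, hi)
        return -mag if rng.random() < cfg.sign_flip_prob else mag

    for i in range(r):
        for j in range(i + 1, r):
            if rng.random() < cfg.p_edge_reg_to_reg:
                W[i, j] = draw_weight()
        for j in range(r, d):
            if rng.random() < cfg.p_edge_reg_to_target:
                W[i, j] = draw_weight()

    if cfg.coregulation and r >= 2:
        for j in range(r, d):
            parents = np.nonzero(W[:r, j])[0]
            if len(parents) == 1:
                others = [i for i in range(r) if i != parents[0]]
                W[rng.choice(others), j] = draw_weight()

    labels = np.zeros(d, dtype=bool)
    labels[:r] = True
    gene_ids = [f"REG{i}" for i in range(r)] + [f"TGT{j}" for j in range(t)]
    return GroundTruthGraph(W, labels, gene_ids)


def _topological_order(W: np.ndarray) -> list[int]:
    """Kahn order of the support; assumes acyclic input."""
    d = W.shape[0]
    indeg = (W != 0).sum(axis=0)
    queue = sorted(np.nonzero(indeg == 0)[0])
    order: list[int] = []
    indeg = indeg.copy()
    while queue:
        v = queue.pop(0)
        order.append(int(v))
        for child in np.nonzero(W[v])[0]:
            indeg[child] -= 1
            if indeg[child] == 0:
                queue.append(int(child))
        queue.sort()
    return order


def simulate_linear_sem(truth: GroundTruthGraph, cfg: SimConfig) -> ExpressionMatrix:
    """Draw observational samples from the linear SEM defined by the truth.

    Columns are filled in topological order: each gene is the weighted sum
    of its parents plus i.i.d. noise (Gaussian or Gumbel, sd ``noise_sd``).
    """
    if not is_acyclic(WeightedGraph(truth.W_true)):
        raise ValueError("cannot simulate from a cyclic graph")
    rng = np.random.default_rng(cfg.seed % 2**31)
    n, d = cfg.n_samples, truth.n_genes
    X = np.zeros((n, d))
    for j in _topological_order(truth.W_true):
        if cfg.noise_dist == "gumbel":
            # scale chosen so the noise sd equals noise_sd
            scale = cfg.noise_sd * np.sqrt(6) / np.pi
            eps = rng.gumbel(loc=-scale * np.euler_gamma, scale=scale, size=n)
        else:
            eps = rng.normal(scale=cfg.noise_sd, size=n)
        X[:, j] = X @ truth.W_true[:, j] + eps
    genes = list(truth.gene_ids)
    x = ExpressionMatrix(X, genes)
    if cfg.latent_confounding and cfg.n_latent > 0:
        keep = np.ones(d, dtype=bool)
        regs = np.nonzero(truth.regulator_labels)[0]
        hidden = rng.choice(regs, size=min(cfg.n_latent, len(regs)), replace=False)
        keep[hidden] = False
        x = ExpressionMatrix(X[:, keep], [g for g, k in zip(genes, keep) if k])
    return x


def sem_covariance(truth: GroundTruthGraph, noise_sd: float = 1.0) -> np.ndarray:
    """Analytic covariance (I - W)^-T Sigma_eps (I - W)^-1 of the linear SEM."""
    d = truth.n_genes
    M = np.linalg.inv(np.eye(d) - truth.W_true)
    return noise_sd**2 * M.T @ M


def write_fixture_pair(truth: GroundTruthGraph, x: ExpressionMatrix, prefix: str) -> tuple[str, str]:
    """Emit matched (expression TSV, truth edge-list TSV) files for CLI tests."""
    from .io import write_expression, write_truth

    expr_path = f"{prefix}_expression.tsv"
    truth_path = f"{prefix}_truth.tsv"
    write_expression(x, expr_path)
    write_truth(truth, truth_path)
    return expr_path, truth_path
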