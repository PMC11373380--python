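"""Model/Results interface for the three causal discovery estimators.

Three model classes share one pattern: construct from a samples x genes
matrix (ndarray, DataFrame or :class:`ExpressionMatrix`), call ``fit()`` for
a single deterministic pass or ``fit_bootstrap()`` for the resampling
protocol, and receive a Results object carrying the estimated graph and
diagnostics with a ``summary()`` table.

* :class:`PC` — constraint-based search returning a CPDAG (binary output).
* :class:`NOTEARS` — unconstrained continuous optimization (weighted output).
* :class:`PCNT` — the hybrid: the PC CPDAG becomes a hard edge mask inside
  the NOTEARS optimization, combining PC's structure/orientation accuracy
  with NOTEARS's signed effect-size estimates.

Bootstrap aggregation follows the benchmarking protocol: resample samples
with replacement, rerun the full algorithm per replicate, and aggregate —
edge presence frequency for the binary-output PC, mean signed weight (absent
edges contributing zero) for the weighted-output methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .graph import (
    CPDAG,
    ConstraintMask,
    ExpressionMatrix,
    WeightedGraph,
    break_cycles_by_weight,
    select_top_k_edges,
)
from .notears import NotearsConfig, NotearsFit, build_constraint_mask, fit_notears
from .pc import run_pc

logger = logging.getLogger(__name__)


@dataclass
class PcntConfig:
    """Bundled configuration for the hybrid pipeline and its bootstrap."""

    alpha: float = 0.05
    max_cond_size: int = 3
    notears: NotearsConfig = field(default_factory=NotearsConfig)
    n_bootstrap: int = 10
    top_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be at least 1")


def _coerce_data(data, gene_ids=None) -> ExpressionMatrix:
    if isinstance(data, ExpressionMatrix):
        return data
    if isinstance(data, pd.DataFrame):
        return ExpressionMatrix(
            data.to_numpy(dtype=float),
            [str(c) for c in data.columns],
            [str(i) for i in data.index],
        )
    return ExpressionMatrix(np.asarray(data, dtype=float), list(gene_ids or []))


class CausalDiscoveryResults:
    """Base results: the estimated weighted graph plus provenance."""

    method = "base"

    def __init__(self, model: "_CausalDiscoveryModel", graph: WeightedGraph):
        self.model = model
        self.graph = graph

    @property
    def weights(self) -> pd.DataFrame:
        g = self.graph
        return pd.DataFrame(g.W, index=g.gene_ids, columns=g.gene_ids)

    def to_edge_list(self) -> pd.DataFrame:
        """Edges sorted by |weight| descending with deterministic tie-break."""
        g = self.graph
        rows = [
            (g.gene_ids[i], g.gene_ids[j], w)
            for i, j, w in sorted(
                g.edges(), key=lambda e: (-abs(e[2]), e[0], e[1])
            )
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def _summary_extra(self) -> list[str]:
        return []

    def summary(self, max_edges: int = 20) -> str:
        g = self.graph
        lines = [
            f"{type(self).__name__}",
            "=" * 58,
            f"method: {self.method}    genes: {g.n_genes}    "
            f"samples: {self.model.data.n_samples}",
            f"edges (nonzero weights): {len(g.edges())}",
        ]
        lines += self._summary_extra()
        lines.append("-" * 58)
        lines.append(f"{'source':<16}{'target':<16}{'weight':>12}")
        for _, row in self.to_edge_list().head(max_edges).iterrows():
            lines.append(f"{row.source:<16}{row.target:<16}{row.weight:>12.4f}")
        if len(g.edges()) > max_edges:
            lines.append(f"... {len(g.edges()) - max_edges} more edges")
        lines.append("=" * 58)
        return "\n".join(lines)


class PCResults(CausalDiscoveryResults):
    method = "pc"

    def __init__(self, model, graph, cpdag: CPDAG):
        super().__init__(model, graph)
        self.cpdag = cpdag

    def _summary_extra(self) -> list[str]:
        return [
            f"CPDAG: {len(self.cpdag.directed_edges())} directed, "
            f"{len(self.cpdag.undirected_edges())} undirected edges "
            f"(alpha={self.model.alpha})"
        ]


class NOTEARSResults(CausalDiscoveryResults):
    method = "notears"

    def __init__(self, model, graph, fit: NotearsFit):
        super().__init__(model, graph)
        self.fit_info = fit
        self.converged = fit.converged

    def _summary_extra(self) -> list[str]:
        f = self.fit_info
        return [
            f"converged: {f.converged}    h(W): {f.h_final:.2e}    "
            f"dual iterations: {f.n_dual_iter}"
        ]


class PCNTResults(NOTEARSResults):
    method = "pcnt"

    def __init__(self, model, graph, fit: NotearsFit, cpdag: CPDAG, mask: ConstraintMask):
        super().__init__(model, graph, fit)
        self.cpdag = cpdag
        self.mask = mask

    def _summary_extra(self) -> list[str]:
        return [
            f"PC mask: {int(self.mask.allowed.sum())} permitted directed entries"
        ] + super()._summary_extra()


class BootstrapResults(CausalDiscoveryResults):
    """Aggregate of per-replicate fits.

    For the binary-output PC the weights are edge-presence frequencies in
    [0, 1]; for weighted methods they are means of signed weights with
    absent edges contributing zero.
    """

    def __init__(self, model, graph, n_requested: int, n_success: int, top_k=None):
        super().__init__(model, graph)
        self.method = f"{model.method} (bootstrap)"
        self.n_requested = n_requested
        self.n_success = n_success
        self.top_k = top_k

    def _summary_extra(self) -> list[str]:
        extra = [f"bootstrap replicates: {self.n_success}/{self.n_requested}"]
        if self.top_k is not None:
            extra.append(f"top-k edge selection: k={self.top_k}")
        return extra


class _CausalDiscoveryModel:
    """Shared constructor and bootstrap machinery."""

    method = "base"
    #: binary-output methods aggregate bootstrap replicates by edge frequency
    binary_output = False

    def __init__(self, data, gene_ids=None):
        self.data = _coerce_data(data, gene_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        return cls(df, **kwargs)

    def fit(self) -> CausalDiscoveryResults:  # pragma: no cover - abstract
        raise NotImplementedError

    def _refit_on(self, data: ExpressionMatrix) -> CausalDiscoveryResults:
        """Re-run the estimator on resampled data (same hyperparameters)."""
        clone = self.__class__.__new__(self.__class__)
        clone.__dict__ = {**self.__dict__, "data": data}
        return clone.fit()

    def fit_bootstrap(
        self,
        n_bootstrap: int = 10,
        seed: int = 0,
        top_k: int | None = None,
    ) -> BootstrapResults:
        """Bootstrap the estimator and aggregate edges across replicates.

        Samples (rows) are resampled with replacement; genes never are.
        Replicate b uses the deterministic seed ``seed + b`` so runs are
        independent but reproducible. Failed replicates are skipped with the
        denominator adjusted; every replicate failing is an error.
        """
        if n_bootstrap < 1:
            raise ValueError("n_bootstrap must be at least 1")
        x = self.data
        acc = np.zeros((x.n_genes, x.n_genes))
        n_success = 0
        for b in range(n_bootstrap):
            rng = np.random.default_rng((seed + b) % 2**31)
            idx = rng.integers(0, x.n_samples, size=x.n_samples)
            resampled = ExpressionMatrix(
                x.values[idx], list(x.gene_ids), [f"B{b}_{t}" for t in range(len(idx))]
            )
            try:
                res = self._refit_on(resampled)
            except Exception as exc:  # noqa: BLE001 - replicate isolation
                logger.warning("bootstrap replicate %d failed: %s", b, exc)
                continue
            W = res.graph.W
            acc += (W != 0).astype(float) if self.binary_output else W
            n_success += 1
        if n_success == 0:
            raise RuntimeError("all bootstrap replicates failed")
        graph = WeightedGraph(acc / n_success, list(x.gene_ids))
        if not self.binary_output:
            # replicates are DAGs but their mean need not be: pairs whose
            # orientation flips across resamples leave weight in both
            # directions; keep the dominant direction so the aggregate obeys
            # the acyclic-output contract of weighted methods
            graph = break_cycles_by_weight(graph)
        if top_k is not None:
            graph = select_top_k_edges(graph, top_k)
        return BootstrapResults(self, graph, n_bootstrap, n_success, top_k)


class PC(_CausalDiscoveryModel):
    """PC-stable causal discovery model.

    ``fit()`` runs the conditional-independence search and returns the CPDAG
    both as such and as a binary weighted graph (undirected edges set both
    directed entries to 1, so they count against orientation metrics).
    """

    method = "pc"
    binary_output = True

    def __init__(self, data, gene_ids=None, alpha: float = 0.05, max_cond_size: int = 3):
        super().__init__(data, gene_ids)
        self.alpha = alpha
        self.max_cond_size = max_cond_size

    def fit(self) -> PCResults:
        cpdag = run_pc(self.data, alpha=self.alpha, max_cond_size=self.max_cond_size)
        graph = WeightedGraph(cpdag.amat.astype(float), list(cpdag.gene_ids))
        return PCResults(self, graph, cpdag)


class NOTEARS(_CausalDiscoveryModel):
    """Unconstrained linear NOTEARS model (data standardized per gene)."""

    method = "notears"

    def __init__(self, data, gene_ids=None, config: NotearsConfig | None = None, **overrides):
        super().__init__(data, gene_ids)
        cfg = config or NotearsConfig()
        self.config = replace(cfg, **overrides) if overrides else cfg

    def fit(self) -> NOTEARSResults:
        fit = fit_notears(self.data.standardized(), mask=None, cfg=self.config)
        return NOTEARSResults(self, fit.graph, fit)


class PCNT(_CausalDiscoveryModel):
    """Hybrid PC + NOTEARS model.

    ``fit()`` first runs PC, converts the CPDAG into a hard edge mask
    (directed edges enforce their orientation, undirected edges leave both
    directions free), then solves the masked NOTEARS program. The result
    inherits PC's structure while carrying signed effect estimates.
    """

    method = "pcnt"

    def __init__(
        self,
        data,
        gene_ids=None,
        alpha: float = 0.05,
        max_cond_size: int = 3,
        config: NotearsConfig | None = None,
        **overrides,
    ):
        super().__init__(data, gene_ids)
        self.alpha = alpha
        self.max_cond_size = max_cond_size
        cfg = config or NotearsConfig()
        self.config = replace(cfg, **overrides) if overrides else cfg

    def fit(self) -> PCNTResults:
        cpdag = run_pc(self.data, alpha=self.alpha, max_cond_size=self.max_cond_size)
        mask = build_constraint_mask(cpdag)
        if not mask.allowed.any():
            warnings.warn(
                "PC returned an empty CPDAG; the constrained fit is the zero graph",
                stacklevel=2,
            )
        fit = fit_notears(self.data.standardized(), mask=mask, cfg=self.config)
        return PCNTResults(self, fit.graph, fit, cpdag, mask)


_MODELS = {"pc": PC, "notears": NOTEARS, "pcnt": PCNT}


def _make_model(x: ExpressionMatrix, algorithm: str, cfg: PcntConfig):
    if algorithm == "pc":
        return PC(x, alpha=cfg.alpha, max_cond_size=cfg.max_cond_size)
    if algorithm == "notears":
        return NOTEARS(x, config=cfg.notears)
    if algorithm == "pcnt":
        return PCNT(x, alpha=cfg.alpha, max_cond_size=cfg.max_cond_size, config=cfg.notears)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {sorted(_MODELS)}")


def run_pcnt(x: ExpressionMatrix, cfg: PcntConfig | None = None) -> WeightedGraph:
    """Single deterministic hybrid pass: PC -> mask -> constrained NOTEARS."""
    cfg = cfg or PcntConfig()
    return PCNT(
        x, alpha=cfg.alpha, max_cond_size=cfg.max_cond_size, config=cfg.notears
    ).fit().graph


def bootstrap_aggregate(
    x: ExpressionMatrix, algorithm: str, cfg: PcntConfig | None = None
) -> WeightedGraph:
    """Bootstrap ``algorithm`` over resampled data and aggregate edge weights."""
    cfg = cfg or PcntConfig()
    model = _make_model(x, algorithm, cfg)
    return model.fit_bootstrap(
        n_bootstrap=cfg.n_bootstrap, seed=cfg.seed, top_k=cfg.top_k
    ).graph
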