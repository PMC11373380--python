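"""End-to-end benchmarking: ground truth -> subsampling -> simulation -> methods -> metrics.

The protocol mirrors the regulator/target evaluation workflow: induced
subgraphs of 5 regulators + 25 targets are drawn from the ground-truth graph
(20 repeats by default, connectivity not required), observational data are
simulated from each subgraph, every method is bootstrap-aggregated on that
data, edges are cut to the top k by absolute weight, and the result is
scored against the subgraph truth. Everything is seeded, so identical
configurations give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .metrics import evaluate, subsample_ground_truth
from .model import PcntConfig, bootstrap_aggregate
from .simulate import SimConfig, generate_star_dag, simulate_linear_sem


@dataclass
class BenchmarkConfig:
    """Subsampling counts plus the per-method pipeline configuration."""

    n_subsample_regulators: int = 5
    n_subsample_targets: int = 25
    n_repeats: int = 20
    pipeline: PcntConfig = field(default_factory=lambda: PcntConfig(top_k=40))


def run_benchmark(
    sim_cfg: SimConfig,
    methods: tuple[str, ...] = ("pc", "notears", "pcnt"),
    bench_cfg: BenchmarkConfig | None = None,
) -> pd.DataFrame:
    """One row of metrics per (repeat, method); failures recorded, not fatal.

    Rows carry all :class:`~pcnt.metrics.EvaluationReport` fields plus
    ``repeat``, ``method`` and an ``error`` column that is empty on success.
    """
    bench_cfg = bench_cfg or BenchmarkConfig()
    truth = generate_star_dag(sim_cfg)
    subgraphs = subsample_ground_truth(
        truth,
        n_regulators=bench_cfg.n_subsample_regulators,
        n_targets=bench_cfg.n_subsample_targets,
        n_repeats=bench_cfg.n_repeats,
        seed=sim_cfg.seed,
    )
    rows = []
    for r, sub in enumerate(subgraphs):
        data_cfg = replace(sim_cfg, seed=(sim_cfg.seed + 7919 * (r + 1)) % 2**31)
        x = simulate_linear_sem(sub, data_cfg)
        for m, method in enumerate(methods):
            cell_cfg = replace(
                bench_cfg.pipeline,
                seed=(sim_cfg.seed + 104729 * (r + 1) + m) % 2**31,
            )
            row: dict[str, object] = {"repeat": r, "method": method, "error": ""}
            try:
                graph = bootstrap_aggregate(x, method, cell_cfg)
                row.update(evaluate(graph, sub).as_dict())
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of each metric per method, NaN cells excluded."""
    metric_cols = [
        c for c in table.columns if c not in ("repeat", "method", "error")
    ]
    ok = table[table["error"] == ""]
    return ok.groupby("method")[metric_cols].mean(numeric_only=True)
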