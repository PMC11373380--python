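"""Delimited-text readers/writers and the run manifest.

Edge-list files follow the package-wide orientation convention (the source
gene causes the target gene) and carry two comment lines declaring the full
gene set and the regulator labels so that isolated genes survive a
write/read round trip. Expression tables are plain TSV/CSV with sample rows
and gene columns (a transposed layout is handled by the ``orientation``
flag).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .graph import ExpressionMatrix, GroundTruthGraph, WeightedGraph

_ORIENTATION_COMMENT = "# orientation: source causes target (W[source, target])"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(
    path: str | Path, orientation: str = "samples_by_genes"
) -> ExpressionMatrix:
    """Load a delimited expression table (first row/column are labels).

    ``orientation='genes_by_samples'`` transposes on load. Missing or
    non-numeric cells are rejected with their row/column coordinates.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if orientation == "samples_by_genes":
        # pandas silently renames duplicate header fields; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
        dups = {h for h in header if header.count(h) > 1}
        if dups:
            raise ValueError(f"{path}: duplicate gene id {sorted(dups)[0]!r}")
    if orientation == "genes_by_samples":
        df = df.T
    bad = df.isna() | df.apply(lambda c: ~pd.to_numeric(c, errors="coerce").notna())
    if bad.any().any():
        r, c = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValueError(
            f"{path}: missing or non-numeric value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    pd.DataFrame(x.values, index=x.sample_ids, columns=x.gene_ids).to_csv(
        path, sep=_sep_for(path)
    )


def _write_edge_table(
    path: Path, genes: list[str], rows: list[tuple], header: list[str], regulators=None
) -> None:
    with open(path, "w") as fh:
        fh.write(_ORIENTATION_COMMENT + "\n")
        fh.write("# genes: " + ",".join(genes) + "\n")
        if regulators is not None:
            fh.write("# regulators: " + ",".join(regulators) + "\n")
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_edges(g: WeightedGraph, path: str | Path) -> None:
    """Edge-list TSV ``source target weight`` at full float precision."""
    rows = [
        (g.gene_ids[i], g.gene_ids[j], repr(w))
        for i, j, w in sorted(g.edges(), key=lambda e: (-abs(e[2]), e[0], e[1]))
    ]
    _write_edge_table(Path(path), g.gene_ids, rows, ["source", "target", "weight"])


def write_truth(truth: GroundTruthGraph, path: str | Path) -> None:
    """Ground-truth edge list with a ``regulator`` column for the source gene."""
    labels = dict(zip(truth.gene_ids, truth.regulator_labels))
    rows = [
        (truth.gene_ids[i], truth.gene_ids[j], repr(w), str(bool(labels[truth.gene_ids[i]])))
        for i, j, w in sorted(
            truth.as_weighted_graph().edges(), key=lambda e: (-abs(e[2]), e[0], e[1])
        )
    ]
    _write_edge_table(
        Path(path),
        truth.gene_ids,
        rows,
        ["source", "target", "weight", "regulator"],
        regulators=[g for g, lab in labels.items() if lab],
    )


def _read_edge_file(path: Path) -> tuple[pd.DataFrame, list[str] | None, list[str] | None]:
    genes = regulators = None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# genes:"):
            genes = [g for g in line.split(":", 1)[1].strip().split(",") if g]
        elif line.startswith("# regulators:"):
            regulators = [g for g in line.split(":", 1)[1].strip().split(",") if g]
        elif not line.startswith("#") and line.strip():
            body.append(line)
    if not body:
        raise ValueError(f"{path}: no header line")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t", float_precision="round_trip")
    return df, genes, regulators


def _edges_to_matrix(df: pd.DataFrame, genes: list[str], path: Path) -> np.ndarray:
    index = {g: i for i, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    for _, row in df.iterrows():
        s, t = str(row["source"]), str(row["target"])
        for g in (s, t):
            if g not in index:
                raise ValueError(f"{path}: edge references unknown gene {g!r}")
        W[index[s], index[t]] = float(row["weight"])
    return W


def read_edges(path: str | Path, gene_ids: list[str] | None = None) -> WeightedGraph:
    """Read an edge-list TSV back into a weighted graph."""
    path = Path(path)
    df, genes, _ = _read_edge_file(path)
    genes = gene_ids or genes
    if genes is None:
        genes = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    return WeightedGraph(_edges_to_matrix(df, genes, path), list(genes))


def read_truth(path: str | Path, gene_ids: list[str] | None = None) -> GroundTruthGraph:
    """Read a ground-truth edge list.

    Regulator labels come from the ``# regulators:`` comment or a
    ``regulator`` column when present, otherwise a gene is a regulator iff
    it has at least one outgoing edge.
    """
    path = Path(path)
    df, genes, regulators = _read_edge_file(path)
    genes = gene_ids or genes
    if genes is None:
        genes = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    W = _edges_to_matrix(df, genes, path)
    if regulators is not None:
        labels = np.array([g in set(regulators) for g in genes])
    elif "regulator" in df.columns:
        flagged = {
            str(row["source"])
            for _, row in df.iterrows()
            if str(row["regulator"]).strip().lower() in ("true", "1", "yes")
        }
        labels = np.array([(g in flagged) or bool((W[i] != 0).any()) for i, g in enumerate(genes)])
    else:
        labels = (W != 0).any(axis=1)
    return GroundTruthGraph(W, labels, list(genes))


def write_adjacency(g: WeightedGraph, path: str | Path) -> None:
    """Dense adjacency matrix CSV (rows cause columns)."""
    pd.DataFrame(g.W, index=g.gene_ids, columns=g.gene_ids).to_csv(path)


def write_sif(g: WeightedGraph, path: str | Path) -> None:
    """SIF export for network viewers; interaction is the weight sign."""
    with open(path, "w") as fh:
        for i, j, w in sorted(g.edges(), key=lambda e: (-abs(e[2]), e[0], e[1])):
            rel = "activates" if w > 0 else "represses"
            fh.write(f"{g.gene_ids[i]}\t{rel}\t{g.gene_ids[j]}\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a CLI run."""

    command: str
    config: dict
    seed: int
    version: str
    input_checksums: dict[str, str]
    timestamp: str


def write_manifest(
    out_dir: str | Path, command: str, config, seed: int, inputs: list[str | Path]
) -> Path:
    cfg = asdict(config) if is_dataclass(config) else dict(config)
    manifest = RunManifest(
        command=command,
        config=_jsonable(cfg),
        seed=seed,
        version=__version__,
        input_checksums={str(p): _sha256(p) for p in inputs},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
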