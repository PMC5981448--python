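"""Readers and writers for the flat-file formats the pipeline consumes.

All tabular formats are TSV (CSV accepted by extension): expression matrices
with miRNA ids in the first column and sample ids in the header, metadata
with survival columns, edge tables, disease-gene ranks, and GMT pathway
collections. Networks export as a flat edge list plus GraphML.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .preprocess import ExpressionMatrix, SampleLabels, dichotomize_survival
from .regnet import RegulatoryNetwork


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#")
    return ExpressionMatrix.from_frame(df)


def write_expression(mat: ExpressionMatrix, path) -> None:
    mat.to_frame().to_csv(path, sep=_sep(path), index_label="mirna_id")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"metadata {path} lacks a sample_id column")
    return df


def labels_from_metadata(meta: pd.DataFrame, cutoff_months: float = 24.0) -> SampleLabels:
    """Build survival labels from a metadata table.

    Uses a precomputed ``class`` column when present; otherwise dichotomises
    ``survival_months`` at the cutoff, treating a truthy ``alive`` column as
    long survival.
    """
    if "class" in meta.columns and meta["class"].notna().all():
        sm = meta["survival_months"].to_numpy(float) if "survival_months" in meta.columns else None
        return SampleLabels(list(meta["sample_id"]), meta["class"].to_numpy(object), sm)
    if "survival_months" not in meta.columns:
        raise ValueError("metadata needs survival_months or a class column")
    alive = meta["alive"].astype(bool).to_numpy() if "alive" in meta.columns else None
    return dichotomize_survival(
        meta["sample_id"], meta["survival_months"], alive, cutoff_months
    )


def read_mirna_targets(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype=str)
    need = {"mirna_id", "gene_id", "evidence", "database"}
    if not need <= set(df.columns):
        raise ValueError(f"miRNA-target table {path} needs columns {sorted(need)}")
    return df


def read_tf_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype=str)
    if not {"tf_gene_id", "target_gene_id"} <= set(df.columns):
        raise ValueError(f"TF table {path} needs columns tf_gene_id, target_gene_id")
    return df


def read_disease_ranks(path) -> dict[str, int]:
    df = pd.read_csv(path, sep=_sep(path), comment="#", dtype={"gene_id": str, "rank": int})
    if not {"gene_id", "rank"} <= set(df.columns):
        raise ValueError(f"disease-gene table {path} needs columns gene_id, rank")
    return dict(zip(df["gene_id"], df["rank"].astype(int)))


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one gene set per line — name, description, then gene ids, tab-separated."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def write_network(net: RegulatoryNetwork, out_dir) -> None:
    """Flat edge list TSV (source, target, edge_type) plus GraphML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net.edge_frame().to_csv(out / "network_edges.tsv", sep="\t", index=False)
    G = net.graph.copy()
    for n in G.nodes:  # GraphML cannot hold None attribute values
        if G.nodes[n].get("rank") is None:
            G.nodes[n].pop("rank", None)
    nx.write_graphml(G, out / "network.graphml")


def read_network_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def write_fr_table(fr_tab, path) -> None:
    fr_tab.to_series().rename_axis("mirna_id").to_csv(path, sep="\t", header=["FR"])


def read_fr_table(path):
    from .regnet import FRTable

    s = pd.read_csv(path, sep="\t", index_col=0, comment="#")["FR"]
    eps = float(min(s.min(), 1e-3)) if len(s) else 1e-3
    return FRTable(scores=dict(s), epsilon=eps)
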