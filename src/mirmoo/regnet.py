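"""miRNA-mediated regulatory cascade network and functional-relevance scores.

A three-layer directed graph is grown from seed miRNAs: retained miRNA->gene
edges, then transcription-factor (TF) -> target-gene (TG) edges recruited
recursively whenever a newly reached gene is itself a TF, until no new
interaction can be added. Genes carry an optional disease rank (1 = elite,
2 = other associated gene), and each miRNA's functional relevance to the
disease is

    FR(m) = epsilon + sum over reachable ranked genes g of exp(-(d(m, g) + r_g))

where d is the minimum hop count from the miRNA to the gene. Closer targets
and elite (rank-1) genes contribute more; a miRNA reaching no ranked gene
scores exactly epsilon.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

MIRNA = "miRNA"
TF = "TF"
TG = "TG"
EDGE_MIRNA_TARGET = "miRNA-target"
EDGE_TF_TARGET = "TF-target"

DEFAULT_EPSILON = 1e-3


class NetworkError(ValueError):
    """Raised when a network-construction contract is violated."""


@dataclass
class RegulatoryNetwork:
    """Directed typed graph of miRNA, TF and TG nodes with disease ranks."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    annotation_report: dict = field(default_factory=dict)

    @property
    def mirnas(self) -> list[str]:
        return [n for n, t in self.graph.nodes(data="node_type") if t == MIRNA]

    @property
    def genes(self) -> list[str]:
        return [n for n, t in self.graph.nodes(data="node_type") if t in (TF, TG)]

    def rank_of(self, gene: str) -> int | None:
        return self.graph.nodes[gene].get("rank")

    @property
    def ranked_genes(self) -> dict[str, int]:
        return {n: r for n, r in self.graph.nodes(data="rank") if r is not None}

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "edge_type": d["edge_type"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type"])


def filter_mirna_targets(records: pd.DataFrame) -> set[tuple[str, str]]:
    """Evidence-filter miRNA->gene records to a deduplicated edge set.

    A (miRNA, gene) pair is retained iff it has at least one experimentally
    validated record, or predicted records from at least two distinct source
    databases. Input columns: mirna_id, gene_id, evidence, database.
    """
    required = {"mirna_id", "gene_id", "evidence", "database"}
    missing = required - set(records.columns)
    if missing:
        raise NetworkError(f"missing columns in target table: {sorted(missing)}")

    validated: set[tuple[str, str]] = set()
    predicted_dbs: dict[tuple[str, str], set[str]] = {}
    for lineno, rec in enumerate(records.itertuples(index=False), start=1):
        ev = str(rec.evidence).strip().lower()
        db = str(rec.database).strip()
        if ev not in ("validated", "predicted") or not db or db.lower() == "nan":
            raise NetworkError(
                f"malformed miRNA-target record at line {lineno}: "
                f"evidence={rec.evidence!r} database={rec.database!r}"
            )
        key = (str(rec.mirna_id), str(rec.gene_id))
        if ev == "validated":
            validated.add(key)
        else:
            predicted_dbs.setdefault(key, set()).add(db)

    kept = set(validated)
    kept.update(k for k, dbs in predicted_dbs.items() if len(dbs) >= 2)
    return kept


def construct_cascade_network(
    mirna_edges: set[tuple[str, str]] | list[tuple[str, str]],
    tf_edges: pd.DataFrame,
    seed_mirnas,
) -> RegulatoryNetwork:
    """Grow the cascade network from seed miRNAs to a fixed point.

    Starts with the seeds' retained target edges, then repeatedly adds the
    global TF->TG edges of every reached gene that is a TF, until no new
    interaction can be added. TF->TF cycles terminate via the visited set.
    Every node in the result is reachable from some seed miRNA.
    """
    seeds = list(dict.fromkeys(str(m) for m in seed_mirnas))
    if not seeds:
        raise NetworkError("seed miRNA list is empty")
    if not {"tf_gene_id", "target_gene_id"} <= set(tf_edges.columns):
        raise NetworkError("TF table needs columns tf_gene_id, target_gene_id")

    tf_map: dict[str, list[str]] = {}
    for rec in tf_edges.itertuples(index=False):
        tf_map.setdefault(str(rec.tf_gene_id), []).append(str(rec.target_gene_id))

    G = nx.DiGraph()
    frontier: deque[str] = deque()
    seen_genes: set[str] = set()
    seed_set = set(seeds)
    for m in seeds:
        G.add_node(m, node_type=MIRNA)
        targets = sorted({g for mm, g in mirna_edges if mm == m})
        if not targets:
            logger.warning("seed miRNA %s has no retained targets", m)
        for g in targets:
            G.add_edge(m, g, edge_type=EDGE_MIRNA_TARGET)
            if g not in seen_genes:
                seen_genes.add(g)
                frontier.append(g)

    while frontier:
        g = frontier.popleft()
        for tgt in tf_map.get(g, ()):
            G.add_edge(g, tgt, edge_type=EDGE_TF_TARGET)
            if tgt not in seen_genes:
                seen_genes.add(tgt)
                frontier.append(tgt)

    for n in G.nodes:
        if n in seed_set:
            continue
        # a gene acting as a regulator anywhere in the network is a TF
        is_tf = any(d["edge_type"] == EDGE_TF_TARGET for _, _, d in G.out_edges(n, data=True))
        G.nodes[n]["node_type"] = TF if is_tf else TG
    return RegulatoryNetwork(G)


def annotate_disease_genes(net: RegulatoryNetwork, ranks: dict[str, int]) -> RegulatoryNetwork:
    """Attach disease ranks (1 = elite, 2 = other) to matching gene nodes.

    Matching is exact string after case normalisation on both sides. The
    matched/unmatched tally is stored on ``net.annotation_report``.
    """
    if not ranks:
        raise NetworkError("empty disease-gene rank table")
    bad = {g: r for g, r in ranks.items() if r not in (1, 2)}
    if bad:
        raise NetworkError(f"disease ranks outside {{1, 2}}: {bad}")

    node_by_casefold = {str(n).casefold(): n for n in net.graph.nodes}
    matched, unmatched = [], []
    for gene, rank in ranks.items():
        node = node_by_casefold.get(str(gene).casefold())
        if node is None:
            unmatched.append(gene)
        else:
            net.graph.nodes[node]["rank"] = int(rank)
            matched.append(gene)
    net.annotation_report = {
        "n_matched": len(matched),
        "n_unmatched": len(unmatched),
        "unmatched": sorted(map(str, unmatched)),
    }
    return net


def shortest_distances(net: RegulatoryNetwork, mirna: str) -> dict[str, int]:
    """Minimum hop counts from a miRNA to every reachable ranked gene.

    Edges are unit weight, so the shortest-path problem reduces to
    breadth-first search; a direct target is at distance 1. Unreachable
    ranked genes are absent from the map.
    """
    if mirna not in net.graph:
        raise NetworkError(f"unknown miRNA {mirna!r}")
    lengths = nx.single_source_shortest_path_length(net.graph, mirna)
    ranked = net.ranked_genes
    return {g: d for g, d in lengths.items() if g in ranked and g != mirna}


def fr_score(net: RegulatoryNetwork, mirna: str, epsilon: float = DEFAULT_EPSILON) -> float:
    """Functional-relevance score of one miRNA (see module docstring)."""
    if epsilon <= 0:
        raise NetworkError("epsilon must be positive")
    ranked = net.ranked_genes
    dists = shortest_distances(net, mirna)
    return epsilon + sum(math.exp(-(d + ranked[g])) for g, d in dists.items())


@dataclass
class FRTable:
    """Immutable per-miRNA functional-relevance lookup table."""

    scores: dict[str, float]
    epsilon: float
    provenance: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        low = {m: s for m, s in self.scores.items() if s < self.epsilon}
        if low:
            raise NetworkError(f"FR below epsilon for {sorted(low)}")

    def __getitem__(self, mirna: str) -> float:
        return self.scores[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.scores

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, name="FR")


def fr_table(net: RegulatoryNetwork, mirnas=None, epsilon: float = DEFAULT_EPSILON) -> FRTable:
    """Compute the FR lookup table for all (or the given) seed miRNAs."""
    ids = list(mirnas) if mirnas is not None else net.mirnas
    ranked = net.ranked_genes
    scores, prov = {}, {}
    for m in ids:
        dists = shortest_distances(net, m)
        scores[m] = epsilon + sum(math.exp(-(d + ranked[g])) for g, d in dists.items())
        prov[m] = dists
    return FRTable(scores=scores, epsilon=epsilon, provenance=prov)
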