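"""Seeded generators of synthetic study data with planted structure.

Emulates the data shapes of a circulating-miRNA prognosis study: a Cq-scale
expression matrix with a planted differentially expressed miRNA signature,
imbalanced two-class survival labels, a three-layer miRNA -> TF -> gene
regulatory network in which the planted miRNAs sit close to elite disease
genes, ranked disease-gene annotations, and pathway gene sets with one set
enriched for the planted miRNAs' targets. Every generator is a pure function
of the scenario seed.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, dichotomize_survival

#: databases a synthetic edge record may cite
_DATABASES = ("dbA", "dbB", "dbC", "dbD")


@dataclass
class SimulationScenario:
    """Study conditions for one synthetic data set.

    Defaults keep the full discovery pipeline tractable on one CPU while
    echoing the real study's structure: ~100 miRNAs over 75 samples with a
    15 short / 60 long class imbalance, an 8-miRNA planted signature shifted
    by one PCR cycle in the short class, and a gene layer an order of
    magnitude larger than the TF layer.
    """

    n_mirna: int = 100
    n_tf: int = 20
    n_tg: int = 500
    n_short: int = 15
    n_long: int = 60
    n_planted: int = 8
    effect_size: float = 1.0  # Cq cycles subtracted in the short class
    noise_sd: float = 0.5  # within-class Cq standard deviation
    missing_rate: float = 0.05
    base_cq: float = 27.0
    baseline_spread: float = 3.0  # per-miRNA baseline offset, uniform half-width
    targets_per_mirna: int = 8
    tf_out_degree: int = 10
    n_elite: int = 10
    n_rank2: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_mirna:
            raise ValueError("planted signature larger than miRNA pool")
        for name in ("missing_rate",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirna)]

    @property
    def planted_signature(self) -> list[str]:
        return self.mirna_ids[: self.n_planted]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:03d}" for i in range(self.n_tf)]

    @property
    def tg_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_tg)]

    @property
    def gene_ids(self) -> list[str]:
        return self.tf_ids + self.tg_ids


def _bfs_distances(adjacency: dict[str, list[str]], source: str) -> dict[str, int]:
    """Plain breadth-first hop counts, independent of the network module."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    dist.pop(source)
    return dist


def simulate_network(scenario: SimulationScenario):
    """miRNA-target records, TF edges, disease ranks and true hop counts.

    Planted miRNAs each receive two direct elite (rank-1) targets so their
    functional relevance clearly exceeds the background. The emitted record
    table includes single-database predicted decoys that the evidence filter
    must drop; the returned truth is computed on the retained edges only.
    """
    sc = scenario
    rng = np.random.default_rng([sc.seed, 1])
    genes = np.array(sc.gene_ids)
    elite = list(rng.choice(genes, size=sc.n_elite, replace=False))
    rest = [g for g in genes if g not in set(elite)]
    rank2 = list(rng.choice(rest, size=min(sc.n_rank2, len(rest)), replace=False))
    ranks = {g: 1 for g in elite} | {g: 2 for g in rank2}

    retained: set[tuple[str, str]] = set()
    records: list[dict] = []
    planted = set(sc.planted_signature)
    for m in sc.mirna_ids:
        targets = set(rng.choice(genes, size=sc.targets_per_mirna, replace=False))
        if m in planted:
            targets |= set(rng.choice(np.array(elite), size=2, replace=False))
        for g in sorted(targets):
            retained.add((m, g))
            if rng.random() < 0.6:
                records.append(
                    {"mirna_id": m, "gene_id": g, "evidence": "validated",
                     "database": str(rng.choice(_DATABASES))}
                )
            else:
                for db in rng.choice(_DATABASES, size=2, replace=False):
                    records.append(
                        {"mirna_id": m, "gene_id": g, "evidence": "predicted",
                         "database": str(db)}
                    )
        # decoy: predicted by a single database only -> must be filtered out
        decoy = str(rng.choice(genes))
        if (m, decoy) not in retained:
            records.append(
                {"mirna_id": m, "gene_id": decoy, "evidence": "predicted",
                 "database": str(rng.choice(_DATABASES))}
            )

    tf_rows = []
    for tf in sc.tf_ids:
        for tgt in rng.choice(genes, size=min(sc.tf_out_degree, len(genes)), replace=False):
            if tgt != tf:
                tf_rows.append({"tf_gene_id": tf, "target_gene_id": str(tgt)})
    # guarantee at least one TF->TF cycle to exercise convergence
    if sc.n_tf >= 2:
        tf_rows.append({"tf_gene_id": sc.tf_ids[0], "target_gene_id": sc.tf_ids[1]})
        tf_rows.append({"tf_gene_id": sc.tf_ids[1], "target_gene_id": sc.tf_ids[0]})

    adjacency: dict[str, list[str]] = {}
    for m, g in sorted(retained):
        adjacency.setdefault(m, []).append(g)
    for row in tf_rows:
        adjacency.setdefault(row["tf_gene_id"], []).append(row["target_gene_id"])
    truth_distances = {m: _bfs_distances(adjacency, m) for m in sc.mirna_ids}

    records_df = pd.DataFrame(records, columns=["mirna_id", "gene_id", "evidence", "database"])
    tf_df = pd.DataFrame(tf_rows, columns=["tf_gene_id", "target_gene_id"]).drop_duplicates()
    return records_df, tf_df, ranks, truth_distances


def simulate_expression(scenario: SimulationScenario):
    """Cq matrix, survival labels and ground truth for one scenario.

    Background Cq values are i.i.d. normal around per-miRNA baselines; the
    planted miRNAs are shifted ``effect_size`` cycles *down* (over-expressed)
    in the short-survival class, so at one cycle the expected fold change is
    exactly 2 under the short-over-long convention. Missingness is completely
    at random, with a guard that no row or column becomes fully missing.
    """
    sc = scenario
    rng = np.random.default_rng([sc.seed, 2])
    n = sc.n_short + sc.n_long
    baselines = sc.base_cq + rng.uniform(-sc.baseline_spread, sc.baseline_spread, sc.n_mirna)
    values = baselines[:, None] + rng.normal(0.0, sc.noise_sd, (sc.n_mirna, n))
    short_cols = np.arange(sc.n_short)
    values[: sc.n_planted][:, short_cols] -= sc.effect_size

    if sc.missing_rate > 0:
        mask = rng.random(values.shape) < sc.missing_rate
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, rng.integers(n)] = False
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[rng.integers(sc.n_mirna), j] = False
        values = values.copy()
        values[mask] = np.nan

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    months = np.concatenate(
        [rng.uniform(3.0, 23.5, sc.n_short), rng.uniform(24.0, 120.0, sc.n_long)]
    )
    labels = dichotomize_survival(sample_ids, months, cutoff_months=24.0)
    mat = ExpressionMatrix(sc.mirna_ids, sample_ids, values)
    truth = {
        "planted_signature": sc.planted_signature,
        "effect_size": sc.effect_size,
        "noise_sd": sc.noise_sd,
        "n_short": sc.n_short,
        "n_long": sc.n_long,
    }
    return mat, labels, truth


def simulate_pathways(
    scenario: SimulationScenario, n_sets: int = 20, set_size: int = 25
) -> dict[str, set[str]]:
    """Random pathway gene sets plus one set enriched in planted targets."""
    sc = scenario
    rng = np.random.default_rng([sc.seed, 3])
    genes = np.array(sc.gene_ids)
    sets = {
        f"pathway_{i + 1:02d}": set(map(str, rng.choice(genes, size=set_size, replace=False)))
        for i in range(n_sets)
    }
    records, _, _, _ = simulate_network(sc)
    planted_targets = sorted(
        set(records[records["mirna_id"].isin(sc.planted_signature)]["gene_id"])
    )
    core = list(rng.choice(planted_targets, size=min(set_size, len(planted_targets)),
                           replace=False))
    sets["pathway_planted"] = set(map(str, core))
    return sets


def write_scenario(scenario: SimulationScenario, out_dir) -> dict[str, str]:
    """Materialise a scenario as the flat files the pipeline consumes."""
    from .io import write_expression, write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat, labels, truth = simulate_expression(scenario)
    records, tf_df, ranks, truth_dist = simulate_network(scenario)

    write_expression(mat, out / "expression.tsv")
    meta = pd.DataFrame(
        {
            "sample_id": labels.sample_ids,
            "survival_months": labels.survival_months,
            "alive": False,
            "class": labels.classes,
        }
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    records.to_csv(out / "mirna_targets.tsv", sep="\t", index=False)
    tf_df.to_csv(out / "tf_targets.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": list(ranks), "rank": list(ranks.values())}).to_csv(
        out / "disease_genes.tsv", sep="\t", index=False
    )
    write_gmt(simulate_pathways(scenario), out / "pathways.gmt")
    truth_all = {
        "scenario": asdict(scenario),
        **truth,
        "distances": truth_dist,
    }
    (out / "truth.json").write_text(json.dumps(truth_all, indent=1))
    return {
        "expression": str(out / "expression.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "mirna_targets": str(out / "mirna_targets.tsv"),
        "tf_targets": str(out / "tf_targets.tsv"),
        "disease_genes": str(out / "disease_genes.tsv"),
        "pathways": str(out / "pathways.gmt"),
        "truth": str(out / "truth.json"),
    }
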