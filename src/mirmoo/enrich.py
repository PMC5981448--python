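"""Hypergeometric over-representation of gene sets with FDR adjustment.

Given the target genes of a signature's miRNAs, each pathway gene set is
tested for over-representation against a gene universe with the exact
hypergeometric upper tail (no normal approximation), and p-values are
adjusted by Benjamini-Hochberg. The same tail statistic backs the
validation-cohort proportion test (a right-sided Fisher exact test on a
2x2 table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    """One gene set's over-representation statistics."""

    set_name: str
    N: int  # universe size
    K: int  # pathway genes in the universe
    n: int  # query genes in the universe
    k: int  # overlap
    p: float
    q: float = float("nan")

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise EnrichError(f"{self.set_name}: overlap {self.k} exceeds min(K, n)")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int, convention: str = "gt") -> float:
    """Exact upper-tail hypergeometric probability.

    ``convention="ge"`` returns P(X >= k); ``convention="gt"`` returns
    P(X > k) for X ~ Hypergeometric(N, K, n). The strict tail is the
    convention of the right-sided exact test this package reproduces.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise EnrichError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    dist = hypergeom(N, K, n)
    if convention == "ge":
        return float(min(1.0, dist.sf(k - 1)))
    if convention == "gt":
        return float(min(1.0, dist.sf(k)))
    raise EnrichError(f"unknown tail convention {convention!r}")


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise EnrichError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_pathways(
    target_genes,
    gene_sets: dict[str, set[str]],
    universe,
    convention: str = "ge",
) -> list[EnrichmentResult]:
    """Over-representation of query genes in each pathway, sorted by p.

    The query is intersected with the universe; each gene set intersecting
    the universe yields one result. The default ``ge`` tail is the textbook
    over-representation probability; use ``gt`` to match a strict right-sided
    exact-test implementation.
    """
    universe = {str(g) for g in universe}
    if not universe:
        raise EnrichError("empty gene universe")
    query = {str(g) for g in target_genes} & universe
    N, n = len(universe), len(query)
    results = []
    for name, genes in gene_sets.items():
        in_universe = {str(g) for g in genes} & universe
        if not in_universe:
            continue
        K = len(in_universe)
        k = len(in_universe & query)
        p = hypergeom_upper_tail(N, K, n, k, convention=convention)
        results.append(EnrichmentResult(set_name=name, N=N, K=K, n=n, k=k, p=p))
    if results:
        qvals = fdr_adjust([r.p for r in results])
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def validation_proportion_test(
    n_signature_tested: int,
    n_signature_significant: int,
    n_background_tested: int,
    n_background_significant: int,
    convention: str = "gt",
) -> float:
    """Right-sided exact test that the signature's hit proportion exceeds the
    background's: Hypergeometric(N = background tested, K = background
    significant, n = signature tested) evaluated at k = signature significant.
    """
    if n_signature_significant > n_signature_tested:
        raise EnrichError("significant count exceeds tested count in signature")
    if n_background_significant > n_background_tested:
        raise EnrichError("significant count exceeds tested count in background")
    return hypergeom_upper_tail(
        N=n_background_tested,
        K=n_background_significant,
        n=n_signature_tested,
        k=n_signature_significant,
        convention=convention,
    )


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"set": r.set_name, "N": r.N, "K": r.K, "n": r.n, "k": r.k, "p": r.p, "q": r.q}
            for r in results
        ],
        columns=["set", "N", "K", "n", "k", "p", "q"],
    )
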