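"""Gene-set over-representation of DMR-related genes.

DMRs map to genes through the annotation (including nearest genes of
intergenic DMRs); each gene set is tested with the upper-tail
hypergeometric probability of the observed hit count against a background
universe, and BH-adjusted across sets.  One-sided over-representation
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .dmr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int   # query genes in the set
    n: int   # query genes in the universe
    K: int   # set genes in the universe
    N: int   # universe size
    p: float
    q: float
    hits: tuple[str, ...]


def map_dmrs_to_genes(annotated_dmrs) -> list[str]:
    """Unique, sorted gene ids carried by an annotated DMR set."""
    return sorted({a.gene_id for a in annotated_dmrs if a.gene_id is not None})


def hypergeom_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) drawing n from N with K successes."""
    return float(hypergeom.sf(k - 1, N, K, n))


def ora_test(
    query_genes,
    universe_genes,
    gene_sets: dict[str, set[str]],
    fdr_report: float = 0.1,
) -> list[EnrichmentResult]:
    """Over-representation of *query_genes* in each gene set.

    Query genes outside the universe are dropped with a warning.  Results
    are sorted by p (ties by set name); callers typically report entries
    with ``q <= fdr_report``.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        query &= universe
    N, n = len(universe), len(query)
    names = sorted(gene_sets)
    rows = []
    for name in names:
        members = gene_sets[name] & universe
        hits = tuple(sorted(query & members))
        rows.append((name, len(hits), len(members), hits))
    pvals = [hypergeom_p(k, N, K, n) for _, k, K, _ in rows]
    qvals = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            set_name=name, k=k, n=n, K=K, N=N, p=float(p), q=float(q), hits=hits
        )
        for (name, k, K, hits), p, q in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set": r.set_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "hits": ",".join(r.hits),
            }
            for r in results
        ]
    )
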