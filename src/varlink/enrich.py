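"""Hypergeometric over-representation analysis (ORA) of gene lists.

For a query of n genes drawn from a universe of N, a set containing K
universe genes, and x genes shared between query and set, the enrichment
p-value is the exact hypergeometric tail P(X >= x) and the fold enrichment
is (x/n) / (K/N).  Benjamini-Hochberg adjustment is available but the
default report filter is the raw p < 0.05 convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .stats import hypergeom_sf

__all__ = ["EnrichmentResult", "hypergeometric_ora", "bh_adjust"]


@dataclass
class EnrichmentResult:
    set_name: str
    n_universe: int
    n_set: int
    n_query: int
    n_overlap: int
    p_value: float
    fold: float
    overlap_genes: Tuple[str, ...] = ()
    q_value: Optional[float] = None


def _upper(genes: Iterable[str]) -> Set[str]:
    return {g.strip().upper() for g in genes if g.strip()}


def hypergeometric_ora(
    query_genes: Iterable[str],
    gene_sets: Sequence[Tuple[str, str, Sequence[str]]],
    universe_genes: Iterable[str],
    max_p: Optional[float] = None,
    adjust: bool = False,
) -> List[EnrichmentResult]:
    """Exact over-representation test of a query against GMT-style gene sets.

    Query genes outside the universe are dropped with a warning; each set is
    intersected with the universe before testing.  Results are sorted by
    p-value; ``max_p`` filters the report (the conventional cutoff is 0.05)
    and ``adjust=True`` adds BH q-values (computed over all sets, before any
    filtering).
    """
    universe = _upper(universe_genes)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = _upper(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped"
        )
        query &= universe
    N, n = len(universe), len(query)
    results: List[EnrichmentResult] = []
    for set_name, _desc, genes in gene_sets:
        members = _upper(genes) & universe
        K = len(members)
        overlap = sorted(query & members)
        x = len(overlap)
        p = hypergeom_sf(x, N, K, n) if K else 1.0
        fold = (x / n) / (K / N) if (n and K) else 0.0
        results.append(
            EnrichmentResult(
                set_name=set_name,
                n_universe=N,
                n_set=K,
                n_query=n,
                n_overlap=x,
                p_value=p,
                fold=fold,
                overlap_genes=tuple(overlap),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    if adjust and results:
        qvals = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qvals):
            r.q_value = q
    if max_p is not None:
        results = [r for r in results if r.p_value < max_p]
    return results


def bh_adjust(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values (delegates to statsmodels)."""
    if len(p_values) == 0:
        return []
    from statsmodels.stats.multitest import multipletests

    _, qvals, _, _ = multipletests(np.asarray(p_values, float), method="fdr_bh")
    return [float(q) for q in qvals]
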