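"""Over-representation of DE gene lists in pathway gene sets.

One-sided hypergeometric tail (equivalent to the one-sided Fisher exact test
for over-representation) against the measured-gene universe, with a raw
p < alpha enrichment call (no multiple-testing correction at this stage).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    pathway_name: str
    overlap_count: int
    set_size: int          # genes of the set present in the universe
    de_size: int
    universe_size: int
    p_value: float
    is_enriched: bool


def hypergeom_tail_p(overlap: int, de_size: int, set_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe_size, set_size, de_size)."""
    if min(overlap, de_size, set_size, universe_size) < 0:
        raise ValueError("counts must be non-negative")
    if de_size > universe_size or set_size > universe_size:
        raise ValueError("de_size and set_size cannot exceed universe_size")
    if overlap > min(de_size, set_size):
        raise ValueError("overlap cannot exceed min(de_size, set_size)")
    if overlap < max(0, de_size + set_size - universe_size):
        raise ValueError("overlap below the feasible minimum")
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, de_size))


def enrich_pathways(
    de_genes: Sequence[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """One result per pathway, restricted to the measured-gene universe.

    Pathways with fewer than two universe genes are dropped with a warning
    (they could never yield a defined interaction-score spread downstream).
    Results are sorted by ascending p, ties by pathway name.
    """
    uni = set(universe)
    de = set(de_genes)
    stray = sorted(de - uni)
    if stray:
        raise ValueError(f"DE genes absent from universe: {stray[:5]}")
    results: list[EnrichmentResult] = []
    n_dropped = 0
    for name in collection.names:
        genes_in_uni = collection.gene_set(name) & uni
        if len(genes_in_uni) < 2:
            n_dropped += 1
            continue
        overlap = len(genes_in_uni & de)
        p = hypergeom_tail_p(overlap, len(de), len(genes_in_uni), len(uni))
        results.append(
            EnrichmentResult(
                pathway_name=name,
                overlap_count=overlap,
                set_size=len(genes_in_uni),
                de_size=len(de),
                universe_size=len(uni),
                p_value=p,
                is_enriched=p < alpha,
            )
        )
    if n_dropped:
        logger.warning("dropped %d pathways with <2 genes in the universe", n_dropped)
    results.sort(key=lambda r: (r.p_value, r.pathway_name))
    return results
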