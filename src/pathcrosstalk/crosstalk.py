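"""Per-sample pathway summaries and the Interaction Score (IS) matrix.

For a pair of pathways X, Y the per-sample interaction score is

    IS = |M_X - M_Y| / (S_X + S_Y)

where M and S are the mean and (n-1) standard deviation of the expression of
the pathway's measured genes in that sample.  Values near zero indicate
maximal cross-talk: the two pathways sit at indistinguishable expression
levels relative to their spreads.  By default M and S are computed on
log2(normalized expression + 1), which stabilises the spread term.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class PathwaySampleStats:
    """Per-sample mean (M) and sd (S) of one pathway's measured genes."""

    pathway: str
    M: pd.Series
    S: pd.Series
    n_genes_used: int
    n_genes_missing: int


@dataclass
class ISMatrix:
    """Samples x unordered-pathway-pairs matrix of interaction scores."""

    values: pd.DataFrame          # index: sample IDs, columns: canonical pair IDs
    class_labels: pd.Series
    n_capped: int = 0             # +inf sentinels replaced by 10x column max

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.columns)


def pathway_sample_stats(
    expr: ExpressionMatrix, pathway_genes: Iterable[str], name: str = ""
) -> PathwaySampleStats:
    """M and S per sample over the pathway's genes present in the matrix.

    Genes absent from the matrix are ignored (their count is logged); fewer
    than two measured genes is an error — such pathways must be dropped
    upstream.
    """
    genes = list(pathway_genes)
    present = [g for g in genes if g in expr.values.index]
    missing = len(genes) - len(present)
    if missing:
        logger.info("pathway %s: %d/%d genes not measured", name or "?", missing, len(genes))
    if len(present) < 2:
        raise ValueError(f"pathway {name or '?'}: fewer than 2 measured genes")
    sub = expr.values.loc[present]
    return PathwaySampleStats(
        pathway=name,
        M=sub.mean(axis=0),
        S=sub.std(axis=0, ddof=1),
        n_genes_used=len(present),
        n_genes_missing=missing,
    )


def interaction_score(mx: float, sx: float, my: float, sy: float) -> float:
    """IS = |Mx - My| / (Sx + Sy); 0 when both numerator and denominator are
    zero, +inf sentinel when only the denominator is."""
    if sx < 0 or sy < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = sx + sy
    num = abs(mx - my)
    if denom == 0.0:
        return 0.0 if num == 0.0 else math.inf
    return num / denom


def build_is_matrix(
    expr: ExpressionMatrix,
    enriched: Sequence[str],
    collection: GeneSetCollection,
    log_transform: bool = True,
    exclude_shared_genes: bool = False,
) -> ISMatrix:
    """IS matrix over all unordered pairs of enriched pathways.

    Rows cover every sample of ``expr`` (both classes: the downstream
    classifier needs case and control rows).  ``expr`` is expected on the
    normalized scale; with ``log_transform`` the stats are computed on
    log2(x+1).  Genes shared by both pathways of a pair contribute to both
    means unless ``exclude_shared_genes``.  Infinite scores are replaced by
    10x the finite column maximum (count logged).
    """
    names = list(enriched)
    if len(names) < 2:
        raise ValueError("no pairs: fewer than 2 enriched pathways")
    values = expr.values
    if log_transform:
        values = np.log2(values + 1.0)
        expr = expr.with_values(values)

    stats = {name: pathway_sample_stats(expr, collection.genes(name), name) for name in names}

    columns: dict[str, np.ndarray] = {}
    n_capped = 0
    for x, y in itertools.combinations(names, 2):
        if exclude_shared_genes:
            shared = collection.gene_set(x) & collection.gene_set(y)
            if shared:
                gx = [g for g in collection.genes(x) if g not in shared]
                gy = [g for g in collection.genes(y) if g not in shared]
                if len([g for g in gx if g in expr.values.index]) < 2 or len(
                    [g for g in gy if g in expr.values.index]
                ) < 2:
                    logger.warning("pair %s|%s skipped: <2 genes after shared-gene exclusion", x, y)
                    continue
                sx_stats = pathway_sample_stats(expr, gx, x)
                sy_stats = pathway_sample_stats(expr, gy, y)
            else:
                sx_stats, sy_stats = stats[x], stats[y]
        else:
            sx_stats, sy_stats = stats[x], stats[y]
        num = (sx_stats.M - sy_stats.M).abs().to_numpy()
        denom = (sx_stats.S + sy_stats.S).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            col = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.where(num == 0, 0.0, np.inf))
        inf_mask = np.isinf(col)
        if inf_mask.any():
            finite = col[~inf_mask]
            cap = 10.0 * float(finite.max()) if finite.size and finite.max() > 0 else 10.0
            col = np.where(inf_mask, cap, col)
            n_capped += int(inf_mask.sum())
        columns[canonical_pair(x, y)] = col

    if n_capped:
        logger.info("capped %d infinite interaction scores at 10x column max", n_capped)
    frame = pd.DataFrame(columns, index=expr.sample_ids)
    frame = frame[sorted(frame.columns)]
    return ISMatrix(frame, expr.class_labels, n_capped)
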