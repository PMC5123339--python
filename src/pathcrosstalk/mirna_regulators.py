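"""miRNA regulators of pathway pairs via k-NN mutual information.

Candidate miRNA targets are called from the Kraskov-Stoegbauer-Grassberger
(KSG, first variant) k-nearest-neighbour mutual-information estimate between
each miRNA and every gene, thresholded against a per-miRNA permutation null
with BH control.  A miRNA is linked to a pathway pair when its targets are
over-represented (hypergeometric p < 0.01) in *both* pathways, and the final
regulator list keeps only miRNAs that are themselves differentially
expressed.

MI is computed on log2(normalized+1) values.  By default the class-mean of
every feature is removed first (within-class centring), so target calling
reflects per-sample covariation rather than shared differential expression —
without this, every DE miRNA trivially shares class-driven information with
every DE gene.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from .diffexpr import DEConfig, bh_adjust, call_de, nb_exact_test, normalize_counts
from .enrichment import hypergeom_tail_p
from .io_formats import CASE, ExpressionMatrix, GeneSetCollection, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class MIConfig:
    """KSG estimation and target-calling settings.

    ``target_rule``: ``"permutation-fdr"`` (default) calls targets whose MI
    beats a pooled per-miRNA permutation null at BH ``alpha``;
    ``"top-quantile"`` keeps genes above the ``top_quantile`` MI quantile.
    ``n_null_genes`` bounds how many gene columns feed each permutation's
    null pool (None: all genes).
    """

    k_neighbors: int = 3
    target_rule: str = "permutation-fdr"
    alpha: float = 0.05
    n_perm: int = 100
    top_quantile: float = 0.95
    n_null_genes: int | None = None
    jitter_scale: float = 1e-10
    center_classes: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        if self.target_rule not in ("permutation-fdr", "top-quantile"):
            raise ValueError(f"unknown target_rule {self.target_rule!r}")


@dataclass
class RegulatorLink:
    """A miRNA linked to both pathways of one pair."""

    mirna_id: str
    pair_id: str
    p_x: float
    p_y: float
    n_targets: int
    mean_case: float = float("nan")
    mean_control: float = float("nan")
    logfc: float = float("nan")
    fdr: float = float("nan")


# ---------------------------------------------------------------------------
# KSG estimator
# ---------------------------------------------------------------------------

def deterministic_jitter(values: np.ndarray, tag: str, scale: float = 1e-10) -> np.ndarray:
    """Break exact ties with tiny noise from a hash-seeded stream.

    The seed derives from ``tag`` (e.g. the feature ID) so the jitter is
    reproducible across runs and platforms; the amplitude is
    ``scale * value range`` (or ``scale`` for constant vectors).
    """
    rng = np.random.default_rng(zlib.crc32(tag.encode()) & 0x7FFFFFFF)
    span = float(np.ptp(values))
    amp = scale * (span if span > 0 else 1.0)
    return values + rng.uniform(-amp, amp, size=values.shape)


def ksg_mi(x, y, k: int = 3) -> float:
    """KSG (variant 1) mutual information estimate in nats.

    MI = psi(k) + psi(n) - <psi(n_x + 1) + psi(n_y + 1)> with max-norm
    neighbourhoods and strict-inequality marginal counts.  The raw estimate
    is returned (it can be slightly negative for independent data); clamp at
    zero downstream where a non-negative value is needed.  Exact ties must
    be broken (jittered) beforehand.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n <= k + 1:
        raise ValueError(f"need n > k+1 points (n={n}, k={k})")
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    # strict |x_j - x_i| < eps_i counts, chunked to bound memory at large n
    nx = np.empty(n, dtype=np.int64)
    ny = np.empty(n, dtype=np.int64)
    chunk = max(1, int(2**22 // n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        e = eps[start:stop, None]
        nx[start:stop] = (np.abs(x[None, :] - x[start:stop, None]) < e).sum(axis=1) - 1
        ny[start:stop] = (np.abs(y[None, :] - y[start:stop, None]) < e).sum(axis=1) - 1
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def _ksg_mi_batch(x: np.ndarray, Y: np.ndarray, k: int, chunk: int = 64) -> np.ndarray:
    """KSG MI of one x against many y rows (small n, O(n^2) broadcasting)."""
    n = x.size
    if n <= k + 1:
        raise ValueError(f"need n > k+1 points (n={n}, k={k})")
    dx = np.abs(x[None, :] - x[:, None])
    base = digamma(k) + digamma(n)
    out = np.empty(Y.shape[0])
    for start in range(0, Y.shape[0], chunk):
        block = Y[start : start + chunk]
        dy = np.abs(block[:, None, :] - block[:, :, None])  # (m, n, n)
        d = np.maximum(dx[None, :, :], dy)
        idx = np.arange(n)
        d[:, idx, idx] = np.inf
        eps = np.partition(d, k - 1, axis=2)[:, :, k - 1]  # (m, n)
        nx = (dx[None, :, :] < eps[:, :, None]).sum(axis=2) - 1
        ny = (dy < eps[:, :, None]).sum(axis=2) - 1
        out[start : start + chunk] = base - (
            digamma(nx + 1) + digamma(ny + 1)
        ).mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# target calling
# ---------------------------------------------------------------------------

def _center_by_class(values: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    out = values.astype(float).copy()
    for mask in (is_case, ~is_case):
        if mask.any():
            out[..., mask] -= out[..., mask].mean(axis=-1, keepdims=True)
    return out


def candidate_targets(
    mirna_profile: pd.Series,
    gene_matrix: ExpressionMatrix,
    config: MIConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """MI of one miRNA against every gene, with target calls.

    Returns a DataFrame indexed by gene with columns ``mi``, ``pvalue``,
    ``fdr`` (NaN under the top-quantile rule) and ``called``.  A constant
    miRNA profile yields an empty result with a warning.
    """
    config = config or MIConfig()
    samples = gene_matrix.sample_ids
    x_raw = mirna_profile.loc[samples].to_numpy(dtype=float)
    if np.ptp(x_raw) == 0:
        logger.warning("constant miRNA profile %s: no targets", mirna_profile.name)
        return pd.DataFrame(columns=["mi", "pvalue", "fdr", "called"])
    Y_raw = gene_matrix.values.to_numpy(dtype=float)
    if config.center_classes:
        is_case = (gene_matrix.class_labels.loc[samples] == CASE).to_numpy()
        x_raw = _center_by_class(x_raw, is_case)
        Y_raw = _center_by_class(Y_raw, is_case)

    name = str(mirna_profile.name or "mirna")
    x = deterministic_jitter(x_raw, name, config.jitter_scale)
    genes = gene_matrix.feature_ids
    Y = np.vstack(
        [deterministic_jitter(Y_raw[i], genes[i], config.jitter_scale) for i in range(len(genes))]
    )
    # constant gene rows can never be targets: their jittered MI is pure noise
    nonconst = np.ptp(Y_raw, axis=1) > 0

    k = config.k_neighbors
    mi = _ksg_mi_batch(x, Y, k)

    if config.target_rule == "top-quantile":
        thr = float(np.quantile(mi[nonconst], config.top_quantile))
        called = (mi > thr) & nonconst
        frame = pd.DataFrame(
            {"mi": mi, "pvalue": np.nan, "fdr": np.nan, "called": called}, index=genes
        )
        return frame.loc[frame["called"]].sort_values("mi", ascending=False)

    rng = np.random.default_rng(seed)
    null_idx = np.flatnonzero(nonconst)
    if config.n_null_genes is not None and config.n_null_genes < null_idx.size:
        null_idx = rng.choice(null_idx, config.n_null_genes, replace=False)
    null_pool = np.empty(config.n_perm * null_idx.size)
    for p in range(config.n_perm):
        xp = x[rng.permutation(x.size)]
        null_pool[p * null_idx.size : (p + 1) * null_idx.size] = _ksg_mi_batch(
            xp, Y[null_idx], k
        )
    null_sorted = np.sort(null_pool)
    n_null = null_sorted.size
    # empirical upper-tail p with add-one correction
    exceed = n_null - np.searchsorted(null_sorted, mi, side="left")
    pvals = (1.0 + exceed) / (1.0 + n_null)
    fdr = bh_adjust(pvals)
    called = (fdr < config.alpha) & nonconst
    frame = pd.DataFrame(
        {"mi": mi, "pvalue": pvals, "fdr": fdr, "called": called}, index=genes
    )
    return frame.loc[frame["called"]].sort_values(
        ["fdr", "mi"], ascending=[True, False]
    )


def link_mirna_pair(
    targets: Sequence[str],
    pair: tuple[str, str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.01,
    mirna_id: str = "",
) -> RegulatorLink | None:
    """Link a miRNA to a pair when its targets are enriched in both pathways."""
    uni = set(universe)
    tset = set(targets)
    if not tset <= uni:
        raise ValueError("targets must be a subset of the universe")
    if not tset:
        return None
    x, y = pair
    ps = []
    for name in (x, y):
        genes = collection.gene_set(name) & uni
        if len(genes) == 0:
            return None
        overlap = len(genes & tset)
        ps.append(hypergeom_tail_p(overlap, len(tset), len(genes), len(uni)))
    p_x, p_y = ps
    if p_x < alpha and p_y < alpha:
        return RegulatorLink(
            mirna_id=mirna_id,
            pair_id=canonical_pair(x, y),
            p_x=p_x,
            p_y=p_y,
            n_targets=len(tset),
        )
    return None


def regulator_scan(
    mirna_counts: ExpressionMatrix,
    gene_expr_log: ExpressionMatrix,
    final_pairs: Sequence[str | tuple[str, str]],
    collection: GeneSetCollection,
    mirna_de_config: DEConfig | None = None,
    mi_config: MIConfig | None = None,
    link_alpha: float = 0.01,
    seed: int = 0,
) -> list[RegulatorLink]:
    """Full regulator scan for the final pathway pairs.

    ``mirna_counts`` are raw miRNA counts (used for the DE filter and the
    reported class means); ``gene_expr_log`` is the log2(normalized+1) gene
    matrix on the same samples.  For every differentially expressed miRNA,
    candidate targets are called by MI and tested for enrichment in both
    pathways of every final pair; links are annotated with the miRNA's
    normalized class means, logFC and FDR.
    """
    mirna_de_config = mirna_de_config or DEConfig(lfc_threshold=0.0)
    mi_config = mi_config or MIConfig()
    if list(mirna_counts.sample_ids) != list(gene_expr_log.sample_ids):
        raise ValueError("miRNA and gene matrices must cover the same samples, in order")

    pairs: list[tuple[str, str]] = []
    for p in final_pairs:
        if isinstance(p, str):
            a, _, b = p.partition("|")
            pairs.append((a, b))
        else:
            pairs.append(tuple(p))  # type: ignore[arg-type]
    if not pairs:
        return []

    de_table = nb_exact_test(mirna_counts, mirna_de_config)
    de_mirnas = call_de(de_table)
    logger.info("regulator scan: %d/%d miRNAs differentially expressed",
                len(de_mirnas), mirna_counts.n_features)
    if not de_mirnas:
        return []

    norm = normalize_counts(mirna_counts).values
    case_cols = mirna_counts.case_samples
    control_cols = mirna_counts.control_samples
    mirna_log = np.log2(normalize_counts(mirna_counts).values + 1.0)

    universe = gene_expr_log.feature_ids
    seeds = np.random.SeedSequence(seed).spawn(len(de_mirnas))
    links: list[RegulatorLink] = []
    for mirna, mseed in zip(de_mirnas, seeds):
        profile = mirna_log.loc[mirna]
        targets = candidate_targets(
            profile, gene_expr_log, mi_config, seed=int(mseed.generate_state(1)[0] & 0x7FFFFFFF)
        )
        if targets.empty:
            continue
        for pair in pairs:
            link = link_mirna_pair(
                list(targets.index), pair, collection, universe, link_alpha, mirna_id=mirna
            )
            if link is not None:
                link.mean_case = float(norm.loc[mirna, case_cols].mean())
                link.mean_control = float(norm.loc[mirna, control_cols].mean())
                link.logfc = float(de_table.frame.loc[mirna, "logfc"])
                link.fdr = float(de_table.frame.loc[mirna, "fdr"])
                links.append(link)
    links.sort(key=lambda l: (l.pair_id, l.mirna_id))
    return links
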