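"""End-to-end analysis object.

:class:`CrosstalkAnalysis` is the model-style entry point: it holds the
matched gene/miRNA count matrices, the pathway collection and a
:class:`RunConfig`; ``fit()`` executes the whole procedure — variance filter,
normalisation, balanced bootstrap loop (DE -> enrichment -> interaction-score
matrix -> per-pair random-forest AUC -> top pairs), frequency ranking,
regulator scan, network build — and returns a :class:`CrosstalkResults`
carrying the estimates, per-pair AUCs, regulator links, the annotated
network, a text ``summary()`` and deterministic writers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import DEConfig, normalize_counts, variance_quantile_filter
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    read_expression_table,
    read_gmt,
    split_pair,
    write_pathway_network,
    write_run_report,
)
from .mirna_regulators import MIConfig, RegulatorLink, regulator_scan
from .pair_selection import (
    BootstrapResult,
    ClassifierConfig,
    FrequencyRanking,
    frequency_rank,
    run_bootstraps,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every tunable of one analysis run, with file paths for CLI use."""

    variance_quantile: float = 0.25
    enrichment_alpha: float = 0.01
    link_alpha: float = 0.01
    de: DEConfig = field(default_factory=DEConfig)
    mirna_de: DEConfig = field(default_factory=lambda: DEConfig(lfc_threshold=0.0))
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    mi: MIConfig = field(default_factory=MIConfig)
    seed: int = 0
    # input/output paths (optional; used by run_pipeline / the CLI)
    gene_counts: str | None = None
    mirna_counts: str | None = None
    labels: str | None = None
    gene_sets: str | None = None
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("de", DEConfig), ("mirna_de", DEConfig),
                         ("classifier", ClassifierConfig), ("mi", MIConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def build_network(ranking: FrequencyRanking, links: list[RegulatorLink]) -> nx.Graph:
    """Annotated pathway/miRNA network of the final top pairs.

    Pathway-pathway edges carry the pair's bootstrap frequency and mean
    AUCs; each regulator link contributes two miRNA-pathway edges (one per
    pathway, annotated with that pathway's enrichment p), so every miRNA
    node has degree >= 2.
    """
    if not ranking.top:
        raise ValueError("ranking is empty")
    g = nx.Graph()
    top = set(ranking.top)
    for pair in ranking.top:
        x, y = split_pair(pair)
        for node in (x, y):
            if node not in g:
                g.add_node(node, kind="pathway")
        g.add_edge(
            x,
            y,
            kind="pair",
            frequency=int(ranking.counts[pair]),
            mean_cv_auc=float(ranking.mean_cv_auc[pair]),
            mean_test_auc=float(ranking.mean_test_auc[pair]),
        )
    for link in links:
        if link.pair_id not in top:
            raise ValueError(f"regulator link references non-final pair {link.pair_id!r}")
        x, y = split_pair(link.pair_id)
        if link.mirna_id not in g:
            g.add_node(link.mirna_id, kind="mirna")
        for node, p in ((x, link.p_x), (y, link.p_y)):
            if g.has_edge(link.mirna_id, node):
                g[link.mirna_id][node]["p_value"] = min(g[link.mirna_id][node]["p_value"], float(p))
            else:
                g.add_edge(link.mirna_id, node, kind="regulates", p_value=float(p))
    return g


@dataclass
class CrosstalkResults:
    """Fitted results: ranked pairs, regulators, network and diagnostics."""

    config: RunConfig
    bootstraps: list[BootstrapResult]
    ranking: FrequencyRanking
    regulators: list[RegulatorLink]
    network: nx.Graph
    stage_counts: dict[str, int]

    @property
    def final_pairs(self) -> list[str]:
        return list(self.ranking.top)

    def pair_table(self) -> pd.DataFrame:
        return self.ranking.as_frame()

    def regulator_table(self) -> pd.DataFrame:
        rows = [
            {
                "mirna": l.mirna_id,
                "pair": l.pair_id,
                "p_x": l.p_x,
                "p_y": l.p_y,
                "n_targets": l.n_targets,
                "mean_case": l.mean_case,
                "mean_control": l.mean_control,
                "logfc": l.logfc,
                "fdr": l.fdr,
            }
            for l in self.regulators
        ]
        return pd.DataFrame(rows, columns=[
            "mirna", "pair", "p_x", "p_y", "n_targets",
            "mean_case", "mean_control", "logfc", "fdr",
        ])

    def summary(self) -> str:
        sc = self.stage_counts
        lines = [
            "Pathway cross-talk analysis",
            "=" * 60,
            f"samples (case/control):     {sc['n_case']}/{sc['n_control']}",
            f"genes after filter:         {sc['n_genes']}",
            f"miRNAs after filter:        {sc['n_mirnas']}",
            f"pathways:                   {sc['n_pathways']}",
            f"bootstraps:                 {sc['n_bootstraps']}",
            f"distinct top pairs:         {sc['n_distinct_pairs']}",
            f"final pairs:                {sc['n_final_pairs']}",
            f"regulator links:            {sc['n_regulator_links']}",
            "",
            "Final pairs (count/bootstraps, mean CV-AUC, mean test-AUC):",
        ]
        for pair in self.ranking.top:
            lines.append(
                f"  {pair:<40s} {self.ranking.counts[pair]:>3d}/{self.ranking.n_bootstraps}"
                f"  {self.ranking.mean_cv_auc[pair]:.3f}  {self.ranking.mean_test_auc[pair]:.3f}"
            )
        if self.regulators:
            lines.append("")
            lines.append("miRNA regulators (miRNA, pair, p_x, p_y):")
            for l in self.regulators:
                lines.append(
                    f"  {l.mirna_id:<12s} {l.pair_id:<40s} {l.p_x:.2e}  {l.p_y:.2e}"
                )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write all report tables, the GraphML network and a JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_run_report(self.bootstraps, self.ranking, self.regulators, outdir)
        write_pathway_network(self.network, outdir / "pathway_network.graphml")
        payload = {
            "package_version": __version__,
            "seed": self.config.seed,
            "stage_counts": self.stage_counts,
            "final_pairs": self.final_pairs,
            "n_regulator_links": len(self.regulators),
        }
        (outdir / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        (outdir / "summary.txt").write_text(self.summary() + "\n")


class CrosstalkAnalysis:
    """The analysis model: matched expression matrices + pathway collection.

    Parameters
    ----------
    gene_counts, mirna_counts
        Raw count matrices (features x samples) with identical samples and
        class labels.
    collection
        Pathway gene sets.
    config
        A :class:`RunConfig`; defaults reproduce the study conventions.
    """

    def __init__(
        self,
        gene_counts: ExpressionMatrix,
        mirna_counts: ExpressionMatrix,
        collection: GeneSetCollection,
        config: RunConfig | None = None,
    ) -> None:
        if list(gene_counts.sample_ids) != list(mirna_counts.sample_ids):
            raise ValueError("gene and miRNA matrices must share samples, in order")
        sizes = gene_counts.class_sizes()
        for lab, n in sizes.items():
            if n < 5:
                raise ValueError(f"class {lab!r} has fewer than 5 samples")
        self.gene_counts = gene_counts
        self.mirna_counts = mirna_counts
        self.collection = collection
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        gene_path: str | Path,
        mirna_path: str | Path,
        label_path: str | Path,
        gmt_path: str | Path,
        config: RunConfig | None = None,
    ) -> "CrosstalkAnalysis":
        genes = read_expression_table(gene_path, label_path)
        mirnas = read_expression_table(mirna_path, label_path)
        mirnas = mirnas.subset_samples(genes.sample_ids)
        return cls(genes, mirnas, read_gmt(gmt_path), config)

    def fit(self, seed: int | None = None) -> CrosstalkResults:
        """Run the full procedure and return the fitted results."""
        cfg = self.config
        if seed is not None:
            cfg.seed = int(seed)
        ss = np.random.SeedSequence(cfg.seed)
        boot_seed, reg_seed = (int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(2))

        genes = variance_quantile_filter(self.gene_counts, cfg.variance_quantile)
        mirnas = variance_quantile_filter(self.mirna_counts, cfg.variance_quantile)
        logger.info("variance filter kept %d genes, %d miRNAs", genes.n_features, mirnas.n_features)

        gene_norm = normalize_counts(genes)
        results = run_bootstraps(
            genes,
            self.collection,
            cfg.de,
            cfg.classifier,
            seed=boot_seed,
            enrichment_alpha=cfg.enrichment_alpha,
            expr_norm=gene_norm,
        )
        ranking = frequency_rank(results, cfg.classifier.top_n)

        gene_log = gene_norm.with_values(np.log2(gene_norm.values + 1.0))
        regulators = (
            regulator_scan(
                mirnas,
                gene_log,
                ranking.top,
                self.collection,
                mirna_de_config=cfg.mirna_de,
                mi_config=cfg.mi,
                link_alpha=cfg.link_alpha,
                seed=reg_seed,
            )
            if ranking.top
            else []
        )
        network = build_network(ranking, regulators) if ranking.top else nx.Graph()

        sizes = genes.class_sizes()
        stage_counts = {
            "n_case": sizes["case"],
            "n_control": sizes["control"],
            "n_genes": genes.n_features,
            "n_mirnas": mirnas.n_features,
            "n_pathways": len(self.collection),
            "n_bootstraps": len(results),
            "n_distinct_pairs": len(ranking.counts),
            "n_final_pairs": len(ranking.top),
            "n_regulator_links": len(regulators),
        }
        assert stage_counts["n_final_pairs"] <= cfg.classifier.top_n
        return CrosstalkResults(
            config=cfg,
            bootstraps=results,
            ranking=ranking,
            regulators=regulators,
            network=network,
            stage_counts=stage_counts,
        )


def run_pipeline(config: RunConfig) -> CrosstalkResults:
    """File-driven end-to-end run: read inputs, fit, write everything."""
    for attr in ("gene_counts", "mirna_counts", "labels", "gene_sets", "outdir"):
        value = getattr(config, attr)
        if value is None:
            raise ValueError(f"config is missing the {attr!r} path")
        if attr != "outdir" and not Path(value).exists():
            raise FileNotFoundError(f"{attr} path does not exist: {value}")
    analysis = CrosstalkAnalysis.from_files(
        config.gene_counts, config.mirna_counts, config.labels, config.gene_sets, config
    )
    results = analysis.fit()
    results.save(config.outdir)
    return results


def demo_run_config(seed: int = 0) -> RunConfig:
    """Scaled-down configuration for the bundled synthetic demonstration.

    Bootstrap count, forest size, fold count and permutation budget are
    reduced to demo problem sizes (10 bootstraps, 10 trees, 3 folds, 30
    permutations against 100 null genes); every statistical rule is the
    package default.
    """
    return RunConfig(
        variance_quantile=0.1,
        classifier=ClassifierConfig(
            n_trees=10, k_folds=3, small_k=3, n_bootstraps=10, top_n=10
        ),
        mi=MIConfig(n_perm=30, n_null_genes=100),
        seed=seed,
    )
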