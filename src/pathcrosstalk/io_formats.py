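"""Readers and writers for every external artefact of the pipeline.

Expression matrices are tab-separated text with features in rows and a header
row of sample IDs; sample class labels live in a separate two-column TSV
(sample, label) so the matrix file stays a plain numeric table.  Pathway
collections use the GMT gene-set format.  Pathway/miRNA networks are written
as GraphML, and run reports as fixed-layout TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
VALID_LABELS = (CASE, CONTROL)


def canonical_pair(a: str, b: str) -> str:
    """Canonical unordered-pair name: the two pathway names sorted and joined by '|'."""
    if a == b:
        raise ValueError(f"a pathway cannot pair with itself: {a!r}")
    return "|".join(sorted((a, b)))


def split_pair(pair_id: str) -> tuple[str, str]:
    a, sep, b = pair_id.partition("|")
    if not sep or not a or not b:
        raise ValueError(f"not a canonical pair id: {pair_id!r}")
    return a, b


@dataclass
class ExpressionMatrix:
    """A features x samples non-negative expression matrix with class labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns.  Entries
        must be finite and non-negative (counts or normalized expression).
    class_labels
        Series mapping every sample ID to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    class_labels: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = sorted(v.index[v.index.duplicated()].unique())
            raise ValueError(f"duplicate feature IDs: {dups}")
        if v.columns.has_duplicates:
            dups = sorted(v.columns[v.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample IDs: {dups}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be >= 0")
        labels = self.class_labels.reindex(v.columns)
        if labels.isna().any():
            missing = sorted(v.columns[labels.isna()])
            raise ValueError(f"samples without class label: {missing}")
        bad = sorted(set(labels.unique()) - set(VALID_LABELS))
        if bad:
            raise ValueError(f"invalid class labels {bad}; expected {VALID_LABELS}")
        self.class_labels = labels

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of(self, label: str) -> list[str]:
        return list(self.class_labels.index[self.class_labels == label])

    @property
    def case_samples(self) -> list[str]:
        return self.samples_of(CASE)

    @property
    def control_samples(self) -> list[str]:
        return self.samples_of(CONTROL)

    def class_sizes(self) -> dict[str, int]:
        return {lab: int((self.class_labels == lab).sum()) for lab in VALID_LABELS}

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)],
            self.class_labels.loc[list(sample_ids)],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.class_labels)

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same samples/labels, new value matrix (e.g. after normalization)."""
        return ExpressionMatrix(values, self.class_labels)


@dataclass
class GeneSetCollection:
    """An ordered pathway -> (description, genes) mapping backed by GMT."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_desc, genes) in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def gene_set(self, name: str) -> frozenset[str]:
        return frozenset(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def size(self, name: str) -> int:
        return len(self.sets[name][1])

    def restricted(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Collection with every set intersected with ``universe`` (empty sets dropped)."""
        uni = set(universe)
        out: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, genes) in self.sets.items():
            kept = tuple(g for g in genes if g in uni)
            if kept:
                out[name] = (desc, kept)
        return GeneSetCollection(out)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample, label) TSV without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"], dtype=str)
    if df["sample"].duplicated().any():
        dups = sorted(df.loc[df["sample"].duplicated(), "sample"].unique())
        raise ValueError(f"duplicate sample IDs in label file: {dups}")
    return pd.Series(df["label"].to_numpy(), index=df["sample"], name="label")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_expression_table(path: str | Path, label_path: str | Path) -> ExpressionMatrix:
    """Read a features x samples TSV plus a sample->class label TSV.

    Samples absent from the label file are dropped with a logged warning.
    Raises on duplicate feature IDs, non-numeric cells, or fewer than two
    samples in either class after the join.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValueError(f"duplicate feature IDs in {path}: {dups}")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        if coerced.isna().any() and not raw[col].isna().any():
            row = raw.index[coerced.isna()][0]
            raise ValueError(f"non-numeric value at feature {row!r}, sample {col!r}")
        raw[col] = coerced
    labels = read_labels(label_path)
    keep = [s for s in raw.columns if s in labels.index]
    dropped = [s for s in raw.columns if s not in labels.index]
    if dropped:
        logger.warning("dropping %d unlabelled samples: %s", len(dropped), dropped)
    raw = raw[keep]
    labels = labels.loc[keep]
    for lab in VALID_LABELS:
        if int((labels == lab).sum()) < 2:
            raise ValueError(f"fewer than 2 samples in class {lab!r}")
    return ExpressionMatrix(raw, labels)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name<TAB>description<TAB>gene...

    Duplicate genes within a set are collapsed (first occurrence kept);
    malformed lines and duplicate set names raise with the line number.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate set name {name!r}")
            if not genes:
                raise ValueError(f"line {lineno}: fewer than 3 fields")
            sets[name] = (desc, tuple(dict.fromkeys(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.description(name)
            genes = "\t".join(collection.genes(name))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# network + report writers
# ---------------------------------------------------------------------------

def write_pathway_network(network: nx.Graph, path: str | Path) -> None:
    """Write the annotated pathway/miRNA network as GraphML.

    Pathway nodes carry ``kind="pathway"``, miRNA nodes ``kind="mirna"``;
    pathway-pathway edges carry frequency and mean AUC attributes,
    miRNA-pathway edges the enrichment p-value.
    """
    nx.write_graphml(network, str(path), named_key_ids=True)


def _fmt(x: float) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if x != x:  # NaN
        return "NA"
    return format(float(x), ".6g")


def write_run_report(results, ranking, links, outdir: str | Path) -> None:
    """Write the fixed-layout TSV report tables for a completed run.

    Tables (all tab-separated, one header line):

    ``pair_frequencies.tsv``
        pair, count, n_boots, mean_cv_auc, mean_test_auc — rows sorted by
        descending count, ties by descending mean CV-AUC, then pair name.
    ``de_genes.tsv``
        feature, times_called, n_boots, mean_logfc, mean_fdr.
    ``enriched_pathways.tsv``
        pathway, times_enriched, n_boots, mean_p.
    ``mirna_regulators.tsv``
        mirna, pair, p_x, p_y, n_targets, mean_case, mean_control, logfc, fdr.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_boots = len(results)

    # pair frequencies
    rows = []
    for pair in ranking.ordered_pairs():
        rows.append(
            (
                pair,
                ranking.counts[pair],
                ranking.n_bootstraps,
                ranking.mean_cv_auc[pair],
                ranking.mean_test_auc[pair],
            )
        )
    with open(outdir / "pair_frequencies.tsv", "w") as fh:
        fh.write("pair\tcount\tn_boots\tmean_cv_auc\tmean_test_auc\n")
        for pair, count, nb, cv, test in rows:
            fh.write(f"{pair}\t{count}\t{nb}\t{_fmt(cv)}\t{_fmt(test)}\n")

    # differentially expressed genes across bootstraps
    de_stats: dict[str, list[tuple[float, float]]] = {}
    for res in results:
        table = res.de_table
        for feat in res.de_genes:
            de_stats.setdefault(feat, []).append(
                (table.loc[feat, "logfc"], table.loc[feat, "fdr"])
            )
    de_rows = sorted(
        ((feat, len(v), float(np.mean([a for a, _ in v])), float(np.mean([b for _, b in v])))
         for feat, v in de_stats.items()),
        key=lambda r: (-r[1], r[0]),
    )
    with open(outdir / "de_genes.tsv", "w") as fh:
        fh.write("feature\ttimes_called\tn_boots\tmean_logfc\tmean_fdr\n")
        for feat, times, lfc, fdr in de_rows:
            fh.write(f"{feat}\t{times}\t{n_boots}\t{_fmt(lfc)}\t{_fmt(fdr)}\n")

    # enriched pathways across bootstraps
    en_stats: dict[str, list[float]] = {}
    for res in results:
        for name, p in res.enriched:
            en_stats.setdefault(name, []).append(p)
    en_rows = sorted(
        ((name, len(ps), float(np.mean(ps))) for name, ps in en_stats.items()),
        key=lambda r: (-r[1], r[0]),
    )
    with open(outdir / "enriched_pathways.tsv", "w") as fh:
        fh.write("pathway\ttimes_enriched\tn_boots\tmean_p\n")
        for name, times, p in en_rows:
            fh.write(f"{name}\t{times}\t{n_boots}\t{_fmt(p)}\n")

    # miRNA regulators
    with open(outdir / "mirna_regulators.tsv", "w") as fh:
        fh.write(
            "mirna\tpair\tp_x\tp_y\tn_targets\tmean_case\tmean_control\tlogfc\tfdr\n"
        )
        for link in sorted(links, key=lambda l: (l.pair_id, l.mirna_id)):
            fh.write(
                f"{link.mirna_id}\t{link.pair_id}\t{_fmt(link.p_x)}\t{_fmt(link.p_y)}"
                f"\t{link.n_targets}\t{_fmt(link.mean_case)}\t{_fmt(link.mean_control)}"
                f"\t{_fmt(link.logfc)}\t{_fmt(link.fdr)}\n"
            )
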