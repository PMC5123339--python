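"""Synthetic matched gene/miRNA cohorts with planted, recoverable structure.

The generator emulates the ingredients of a tumour-vs-normal expression study
at desk scale: negative-binomial counts for genes and miRNAs, two sample
classes, a pathway collection with controlled overlap between neighbouring
pathways, planted differentially expressed features, planted "cross-talk"
pathway pairs whose per-sample interaction score separates the classes, and
planted miRNA regulators coupled to target genes in both pathways of a pair.

Every stochastic stage draws from its own named substream of one global seed,
so stages can be regenerated independently and a dataset is bit-reproducible
from its :class:`SyntheticDesign`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CASE,
    CONTROL,
    ExpressionMatrix,
    GeneSetCollection,
    canonical_pair,
)

_STAGES = ("pathways", "baselines", "effects", "latent", "gene_counts", "mirna_counts")


def pathway_name(i: int) -> str:
    return f"PW{i + 1:02d}"


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"MIR{i + 1:03d}" for i in range(n)]


@dataclass(frozen=True)
class Regulator:
    """A planted miRNA regulator of one pathway pair.

    The miRNA is coupled (through a shared latent per-sample factor, negative
    sign by default) to ``n_targets`` genes in each pathway of ``pair`` with
    target correlation ``rho``, and is additionally planted as differentially
    expressed so the final regulator filter keeps it.
    """

    mirna_index: int
    pair: tuple[str, str]
    rho: float
    n_targets: int


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic cohort.

    The defaults are the bundled demonstration conditions: 500 genes and 50
    miRNAs over 60 case + 60 control samples, 20 pathways, three planted
    cross-talk pairs, two decoy (enriched but unshifted) pathways, and two
    planted miRNA regulators.
    """

    n_genes: int = 500
    n_mirnas: int = 50
    n_case: int = 60
    n_control: int = 60
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (15, 25)
    overlap_fraction: float = 0.1
    baseline_mean_range: tuple[float, float] = (50.0, 150.0)
    dispersion: float = 0.1
    de_fraction: float = 0.05
    de_logfc: float = 2.0
    crosstalk_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("PW01", "PW03", 1.2),
            ("PW05", "PW07", 1.2),
            ("PW09", "PW11", 1.2),
        ]
    )
    decoy_pathways: tuple[str, ...] = ("PW13", "PW15")
    pathway_de_fraction: float = 0.75
    pathway_de_logfc: float = 1.8
    regulators: list[Regulator] = field(
        default_factory=lambda: [
            Regulator(0, ("PW01", "PW03"), 0.8, 4),
            Regulator(1, ("PW05", "PW07"), 0.8, 4),
        ]
    )
    regulator_logfc: float = 1.5
    coupling_sign: int = -1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid pathway_size_range")
        blo, bhi = self.baseline_mean_range
        if not (0 < blo <= bhi):
            raise ValueError("invalid baseline_mean_range")
        if self.coupling_sign not in (-1, 1):
            raise ValueError("coupling_sign must be -1 or +1")
        for reg in self.regulators:
            if not (0.0 < reg.rho < 1.0):
                raise ValueError("regulator rho must be in (0, 1)")
            if not (0 <= reg.mirna_index < self.n_mirnas):
                raise ValueError(f"regulator miRNA index {reg.mirna_index} out of range")

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream of the design seed (documented hierarchy)."""
        idx = _STAGES.index(stage)
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(len(_STAGES))[idx])

    @property
    def enriched_pathways(self) -> list[str]:
        """Pathways that receive balanced-sign planted DE (hence enrichable)."""
        seen: dict[str, None] = {}
        for x, y, _ in self.crosstalk_pairs:
            seen.setdefault(x)
            seen.setdefault(y)
        for d in self.decoy_pathways:
            seen.setdefault(d)
        return list(seen)


@dataclass
class SyntheticTruth:
    """Ground truth record of one generated dataset (the acceptance oracle)."""

    de_gene_ids: frozenset[str]
    de_mirna_ids: frozenset[str]
    crosstalk_pairs: frozenset[str]
    regulator_links: frozenset[tuple[str, str]]
    true_gene_logfc: dict[str, float]
    true_mirna_logfc: dict[str, float]
    regulator_targets: dict[str, tuple[str, ...]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_gene_ids": sorted(self.de_gene_ids),
            "de_mirna_ids": sorted(self.de_mirna_ids),
            "crosstalk_pairs": sorted(self.crosstalk_pairs),
            "regulator_links": sorted(list(t) for t in self.regulator_links),
            "true_gene_logfc": self.true_gene_logfc,
            "true_mirna_logfc": self.true_mirna_logfc,
            "regulator_targets": {k: list(v) for k, v in self.regulator_targets.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            de_gene_ids=frozenset(d["de_gene_ids"]),
            de_mirna_ids=frozenset(d["de_mirna_ids"]),
            crosstalk_pairs=frozenset(d["crosstalk_pairs"]),
            regulator_links=frozenset(tuple(t) for t in d["regulator_links"]),
            true_gene_logfc=d["true_gene_logfc"],
            true_mirna_logfc=d["true_mirna_logfc"],
            regulator_targets={k: tuple(v) for k, v in d["regulator_targets"].items()},
        )


# ---------------------------------------------------------------------------
# pathway collection
# ---------------------------------------------------------------------------

def generate_pathway_collection(design: SyntheticDesign) -> GeneSetCollection:
    """Draw a pathway collection with controlled overlap between neighbours.

    Consecutive pathways share ``floor(overlap_fraction * size)`` genes,
    emulating cross-talk through shared biology; all other membership is
    drawn without replacement from the gene pool.
    """
    rng = design.rng("pathways")
    lo, hi = design.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=design.n_pathways)
    n_shared = [0] + [int(math.floor(design.overlap_fraction * s)) for s in sizes[1:]]
    fresh_needed = int(sizes.sum()) - int(sum(n_shared))
    if fresh_needed > design.n_genes:
        raise ValueError(
            f"infeasible sizing: {fresh_needed} distinct genes needed, "
            f"only {design.n_genes} available"
        )
    pool = [_gene_ids(design.n_genes)[i] for i in rng.permutation(design.n_genes)]
    cursor = 0
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    prev: tuple[str, ...] = ()
    for i, size in enumerate(sizes):
        shared: list[str] = []
        if n_shared[i] > 0:
            shared = [prev[j] for j in rng.choice(len(prev), n_shared[i], replace=False)]
        fresh = pool[cursor : cursor + (int(size) - len(shared))]
        cursor += len(fresh)
        genes = tuple(shared) + tuple(fresh)
        sets[pathway_name(i)] = ("synthetic pathway", genes)
        prev = genes
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _noise_sd_log2(design: SyntheticDesign) -> float:
    # approximate per-feature sd of log2 counts at a typical baseline mean
    mu = math.sqrt(design.baseline_mean_range[0] * design.baseline_mean_range[1])
    return math.sqrt(1.0 / mu + design.dispersion) / math.log(2.0)


@dataclass
class _Plan:
    """Deterministic per-feature effect plan shared by the count draws and
    the analytic expected-IS computation."""

    gene_ids: list[str]
    mirna_ids: list[str]
    mu_gene: np.ndarray
    mu_mirna: np.ndarray
    lfc: np.ndarray           # planted log2 fold changes (genes)
    shift: np.ndarray         # cross-talk log2 mean shifts (genes, case only)
    mlfc: np.ndarray          # planted log2 fold changes (miRNAs)
    latent: list[tuple[int, float, np.ndarray, list[str]]]  # (miRNA idx, a, h, targets)
    regulator_targets: dict[str, tuple[str, ...]]
    regulator_links: set[tuple[str, str]]


def _validate_references(design: SyntheticDesign, collection: GeneSetCollection,
                         gene_ids: list[str]) -> None:
    known = set(gene_ids)
    for name in collection.names:
        if not set(collection.genes(name)) <= known:
            raise ValueError(f"collection pathway {name!r} uses genes outside the design")
    for x, y, _ in design.crosstalk_pairs:
        for p in (x, y):
            if p not in collection:
                raise ValueError(f"cross-talk pair references unknown pathway {p!r}")
    for d in design.decoy_pathways:
        if d not in collection:
            raise ValueError(f"decoy references unknown pathway {d!r}")
    for reg in design.regulators:
        for p in reg.pair:
            if p not in collection:
                raise ValueError(f"regulator references unknown pathway {p!r}")


def _make_plan(design: SyntheticDesign, collection: GeneSetCollection) -> _Plan:
    gene_ids = _gene_ids(design.n_genes)
    mirna_ids = _mirna_ids(design.n_mirnas)
    _validate_references(design, collection, gene_ids)
    gi = {g: i for i, g in enumerate(gene_ids)}
    n_samples = design.n_case + design.n_control

    rng_base = design.rng("baselines")
    blo, bhi = design.baseline_mean_range
    mu_gene = rng_base.uniform(blo, bhi, design.n_genes)
    mu_mirna = rng_base.uniform(blo, bhi, design.n_mirnas)

    # ---- random scattered DE (genes) --------------------------------------
    rng_eff = design.rng("effects")
    lfc = np.zeros(design.n_genes)
    n_rand = int(round(design.de_fraction * design.n_genes))
    if n_rand:
        idx = rng_eff.choice(design.n_genes, n_rand, replace=False)
        signs = rng_eff.choice([-1.0, 1.0], n_rand)
        lfc[idx] = signs * design.de_logfc

    # ---- regulator latent factors + targets (targets reserved before the
    # pathway DE planting so their coupling is not diluted by class shifts) --
    rng_lat = design.rng("latent")
    sigma_n = _noise_sd_log2(design)
    latent: list[tuple[int, float, np.ndarray, list[str]]] = []
    regulator_targets: dict[str, tuple[str, ...]] = {}
    regulator_links: set[tuple[str, str]] = set()
    reserved: set[str] = set()
    for reg in design.regulators:
        h = rng_lat.normal(size=n_samples)
        a = sigma_n * math.sqrt(reg.rho / (1.0 - reg.rho))
        targets: list[str] = []
        for p in reg.pair:
            genes = collection.genes(p)
            quiet = [g for g in genes if g not in reserved and lfc[gi[g]] == 0.0]
            noisy = [g for g in genes if g not in reserved and lfc[gi[g]] != 0.0]
            candidates = quiet if len(quiet) >= reg.n_targets else quiet + noisy
            pick = rng_lat.choice(
                len(candidates), min(reg.n_targets, len(candidates)), replace=False
            )
            chosen = [candidates[j] for j in sorted(pick)]
            targets.extend(chosen)
            reserved.update(chosen)
        mid = mirna_ids[reg.mirna_index]
        regulator_targets[mid] = tuple(targets)
        regulator_links.add((mid, canonical_pair(*reg.pair)))
        latent.append((reg.mirna_index, a, h, targets))

    # ---- balanced-sign DE inside every enrichable pathway: makes the
    # pathway reliably enriched while leaving its mean roughly flat ----------
    for name in design.enriched_pathways:
        genes = collection.genes(name)
        k = int(round(design.pathway_de_fraction * len(genes)))
        available = [g for g in genes if lfc[gi[g]] == 0.0 and g not in reserved]
        picked = rng_eff.choice(len(available), min(k, len(available)), replace=False)
        sign = 1.0
        for j in picked:
            lfc[gi[available[j]]] = sign * design.pathway_de_logfc
            sign = -sign

    # ---- cross-talk mean-gap shifts ----------------------------------------
    shift = np.zeros(design.n_genes)
    for x, y, gap in design.crosstalk_pairs:
        gx, gy = collection.genes(x), collection.genes(y)
        mx = float(np.mean(np.log2(mu_gene[[gi[g] for g in gx]] + 1.0)))
        my = float(np.mean(np.log2(mu_gene[[gi[g] for g in gy]] + 1.0)))
        up, down = (x, y) if mx >= my else (y, x)
        shared = set(gx) & set(gy)
        for g in collection.genes(up):
            if g not in shared:
                shift[gi[g]] += gap / 2.0
        for g in collection.genes(down):
            if g not in shared:
                shift[gi[g]] -= gap / 2.0

    # ---- miRNA differential expression -------------------------------------
    mlfc = np.zeros(design.n_mirnas)
    reg_idx = {reg.mirna_index for reg in design.regulators}
    for i in sorted(reg_idx):
        mlfc[i] = design.regulator_logfc
    n_rand_m = int(round(design.de_fraction * design.n_mirnas))
    free = np.array(sorted(set(range(design.n_mirnas)) - reg_idx))
    if n_rand_m and len(free):
        idx = rng_eff.choice(len(free), min(n_rand_m, len(free)), replace=False)
        signs = rng_eff.choice([-1.0, 1.0], len(idx))
        mlfc[free[idx]] = signs * design.de_logfc

    return _Plan(
        gene_ids=gene_ids,
        mirna_ids=mirna_ids,
        mu_gene=mu_gene,
        mu_mirna=mu_mirna,
        lfc=lfc,
        shift=shift,
        mlfc=mlfc,
        latent=latent,
        regulator_targets=regulator_targets,
        regulator_links=regulator_links,
    )


def generate_dataset(
    design: SyntheticDesign, collection: GeneSetCollection
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate matched gene and miRNA count matrices plus the ground truth.

    Counts are NegBin(per-class mean, common dispersion).  Planted DE features
    have case mean = control mean * 2**logfc.  Each cross-talk pair receives a
    symmetric shift of +-gap_shift/2 on the log2 means of its two pathways, in
    the direction that moves the pathway means apart, so the pair's
    interaction score gap exceeds that of any pair sharing only one shifted
    pathway.  Regulator miRNAs are coupled to their targets through a latent
    per-sample factor and planted DE.
    """
    plan = _make_plan(design, collection)
    gene_ids, mirna_ids = plan.gene_ids, plan.mirna_ids
    gi = {g: i for i, g in enumerate(gene_ids)}
    n_samples = design.n_case + design.n_control
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    labels = pd.Series(
        [CASE] * design.n_case + [CONTROL] * design.n_control, index=sample_ids, name="label"
    )
    is_case = np.array([lab == CASE for lab in labels])

    mu_gene, mu_mirna = plan.mu_gene, plan.mu_mirna
    lfc, shift, mlfc = plan.lfc, plan.shift, plan.mlfc
    regulator_targets = plan.regulator_targets
    regulator_links = plan.regulator_links

    gene_case_mean = mu_gene * np.power(2.0, lfc + shift)
    gene_control_mean = mu_gene

    gene_factor = np.ones((design.n_genes, n_samples))
    mirna_factor = np.ones((design.n_mirnas, n_samples))
    for mirna_index, a, h, targets in plan.latent:
        mirna_factor[mirna_index, :] *= np.power(2.0, a * h)
        for g in targets:
            gene_factor[gi[g], :] *= np.power(2.0, design.coupling_sign * a * h)

    # ---- draw counts ------------------------------------------------------
    gene_mean = np.where(is_case[None, :], gene_case_mean[:, None], gene_control_mean[:, None])
    gene_mean = gene_mean * gene_factor
    mirna_mean = np.where(
        is_case[None, :],
        (mu_mirna * np.power(2.0, mlfc))[:, None],
        mu_mirna[:, None],
    )
    mirna_mean = mirna_mean * mirna_factor

    gene_counts = _nb_draw(design.rng("gene_counts"), gene_mean, design.dispersion)
    mirna_counts = _nb_draw(design.rng("mirna_counts"), mirna_mean, design.dispersion)

    genes = ExpressionMatrix(
        pd.DataFrame(gene_counts, index=gene_ids, columns=sample_ids), labels
    )
    mirnas = ExpressionMatrix(
        pd.DataFrame(mirna_counts, index=mirna_ids, columns=sample_ids), labels
    )

    total_lfc = lfc + shift
    truth = SyntheticTruth(
        de_gene_ids=frozenset(
            g for g, v in zip(gene_ids, total_lfc) if abs(v) > 1.0
        ),
        de_mirna_ids=frozenset(m for m, v in zip(mirna_ids, mlfc) if v != 0.0),
        crosstalk_pairs=frozenset(canonical_pair(x, y) for x, y, _ in design.crosstalk_pairs),
        regulator_links=frozenset(regulator_links),
        true_gene_logfc={g: float(v) for g, v in zip(gene_ids, total_lfc) if v != 0.0},
        true_mirna_logfc={m: float(v) for m, v in zip(mirna_ids, mlfc) if v != 0.0},
        regulator_targets=regulator_targets,
    )
    return genes, mirnas, truth


def simulate(
    design: SyntheticDesign,
) -> tuple[GeneSetCollection, ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Convenience wrapper: pathway collection + matched dataset + truth."""
    collection = generate_pathway_collection(design)
    genes, mirnas, truth = generate_dataset(design, collection)
    return collection, genes, mirnas, truth


def demo_design(seed: int = 0) -> SyntheticDesign:
    """The bundled demonstration design (the class defaults) at a given seed."""
    return SyntheticDesign(seed=seed)


def expected_is_gaps(
    design: SyntheticDesign, collection: GeneSetCollection
) -> dict[str, float]:
    """Analytic between-class gap in expected interaction score per pair.

    Uses the design's per-class expected counts on the log2(mean+1) scale,
    ignoring sampling noise and latent-factor inflation; intended for ranking
    planted against non-planted pairs, not as an exact IS prediction.
    """
    plan = _make_plan(design, collection)
    gi = {g: i for i, g in enumerate(plan.gene_ids)}
    mu = plan.mu_gene
    case_log = np.log2(mu * np.power(2.0, plan.lfc + plan.shift) + 1.0)
    control_log = np.log2(mu + 1.0)

    def stats(vec: np.ndarray, name: str) -> tuple[float, float]:
        rows = [gi[g] for g in collection.genes(name)]
        vals = vec[rows]
        return float(vals.mean()), float(vals.std(ddof=1))

    gaps: dict[str, float] = {}
    names = collection.names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = names[i], names[j]
            mxc, sxc = stats(case_log, x)
            myc, syc = stats(case_log, y)
            mxn, sxn = stats(control_log, x)
            myn, syn = stats(control_log, y)
            is_case = abs(mxc - myc) / (sxc + syc) if sxc + syc > 0 else 0.0
            is_ctrl = abs(mxn - myn) / (sxn + syn) if sxn + syn > 0 else 0.0
            gaps[canonical_pair(x, y)] = abs(is_case - is_ctrl)
    return gaps
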