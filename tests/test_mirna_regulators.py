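import math

import numpy as np
import pandas as pd
import pytest

from pathcrosstalk import (
    ExpressionMatrix,
    GeneSetCollection,
    MIConfig,
    candidate_targets,
    ksg_mi,
    link_mirna_pair,
    regulator_scan,
)
from pathcrosstalk.diffexpr import DEConfig
from pathcrosstalk.mirna_regulators import _ksg_mi_batch, deterministic_jitter

from conftest import small_design


def gaussian_mi(rho: float) -> float:
    return -0.5 * math.log(1.0 - rho**2)


class TestKSGEstimator:
    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 400))
        assert abs(ksg_mi(x, y) - ksg_mi(y, x)) < 1e-9

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(1)
        estimates = [
            ksg_mi(rng.uniform(size=800), rng.uniform(size=800)) for _ in range(5)
        ]
        assert abs(float(np.mean(estimates))) < 0.05

    def test_correlated_gaussian_matches_closed_form(self):
        rng = np.random.default_rng(2)
        rho = 0.9
        cov = [[1.0, rho], [rho, 1.0]]
        estimates = []
        for _ in range(5):
            xy = rng.multivariate_normal([0, 0], cov, size=2000)
            estimates.append(ksg_mi(xy[:, 0], xy[:, 1]))
        assert float(np.mean(estimates)) == pytest.approx(gaussian_mi(rho), abs=0.07)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        xy = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=2000)
        a = ksg_mi(xy[:, 0], xy[:, 1])
        b = ksg_mi(np.exp(xy[:, 0]), xy[:, 1] ** 3)
        assert a == pytest.approx(b, abs=0.05)

    def test_near_functional_dependence_is_large(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=1000)
        y = x + rng.normal(scale=1e-6, size=1000)
        assert ksg_mi(x, y) >= 2.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="equal length"):
            ksg_mi(np.arange(10.0), np.arange(9.0))
        with pytest.raises(ValueError, match="n > k"):
            ksg_mi(np.arange(4.0), np.arange(4.0), k=3)

    def test_batch_agrees_with_single_pair(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=150)
        Y = rng.normal(size=(10, 150))
        batch = _ksg_mi_batch(x, Y, k=3)
        singles = np.array([ksg_mi(x, y, k=3) for y in Y])
        np.testing.assert_allclose(batch, singles, atol=1e-9)

    def test_jitter_is_deterministic_and_tiny(self):
        v = np.arange(50.0)
        a = deterministic_jitter(v, "G1")
        b = deterministic_jitter(v, "G1")
        np.testing.assert_array_equal(a, b)
        assert np.max(np.abs(a - v)) < 1e-7
        assert not np.array_equal(a, deterministic_jitter(v, "G2"))


def _gene_matrix(values, labels=None):
    frame = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(values.shape[0])],
        columns=[f"S{i}" for i in range(values.shape[1])],
    )
    if labels is None:
        half = values.shape[1] // 2
        labels = pd.Series(
            ["case"] * half + ["control"] * (values.shape[1] - half),
            index=frame.columns,
        )
    return ExpressionMatrix(frame, labels)


class TestCandidateTargets:
    config = MIConfig(n_perm=30, n_null_genes=60, center_classes=False)

    def test_null_calls_are_rare(self):
        rng = np.random.default_rng(6)
        fractions = []
        for seed in range(5):
            genes = _gene_matrix(rng.uniform(0, 100, size=(80, 100)))
            x = pd.Series(rng.uniform(0, 100, size=100), index=genes.sample_ids, name="MIRX")
            called = candidate_targets(x, genes, self.config, seed=seed)
            fractions.append(len(called) / genes.n_features)
        assert float(np.mean(fractions)) <= 0.07

    def test_planted_coupled_targets_recovered(self):
        rng = np.random.default_rng(7)
        n, m, planted = 200, 100, 10
        latent = rng.normal(size=n)
        values = rng.normal(size=(m, n))
        a = math.sqrt(0.8 / 0.2)  # target correlation 0.8
        values[:planted] = (-a * latent + rng.normal(size=(planted, n))) / math.hypot(a, 1)
        genes = _gene_matrix(values - values.min() + 1.0)
        x = pd.Series(
            (a * latent + rng.normal(size=n)) - values.min() + 1.0,
            index=genes.sample_ids, name="MIRX",
        )
        called = candidate_targets(x, genes, self.config, seed=0)
        recall = len(set(called.index) & {f"G{i}" for i in range(planted)}) / planted
        assert recall >= 0.9

    def test_constant_gene_never_called(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(1, 50, size=(20, 80))
        values[5] = 7.0
        genes = _gene_matrix(values)
        x = pd.Series(values[5] * 0 + rng.uniform(size=80), index=genes.sample_ids, name="M")
        called = candidate_targets(x, genes, self.config, seed=1)
        assert "G5" not in set(called.index)

    def test_constant_mirna_gives_empty_with_warning(self, caplog):
        rng = np.random.default_rng(9)
        genes = _gene_matrix(rng.uniform(1, 50, size=(10, 40)))
        x = pd.Series(np.full(40, 3.0), index=genes.sample_ids, name="MFLAT")
        with caplog.at_level("WARNING"):
            called = candidate_targets(x, genes, self.config, seed=0)
        assert called.empty
        assert any("constant miRNA" in rec.message for rec in caplog.records)

    def test_class_centering_removes_de_confound(self):
        # a DE miRNA and DE genes share class-driven information; centring
        # must prevent DE genes from being called as targets
        rng = np.random.default_rng(10)
        n_case = n_control = 50
        shift = np.array([3.0] * 30 + [0.0] * 50)  # 30 DE genes
        case = rng.normal(size=(80, n_case)) + shift[:, None]
        ctrl = rng.normal(size=(80, n_control))
        values = np.hstack([case, ctrl])
        genes = _gene_matrix(values - values.min() + 1.0)
        x_raw = np.concatenate(
            [rng.normal(3.0, 1.0, n_case), rng.normal(0.0, 1.0, n_control)]
        )
        x = pd.Series(x_raw - x_raw.min() + 1.0, index=genes.sample_ids, name="MDE")
        pooled = candidate_targets(
            x, genes, MIConfig(n_perm=30, n_null_genes=60, center_classes=False), seed=0
        )
        centred = candidate_targets(
            x, genes, MIConfig(n_perm=30, n_null_genes=60, center_classes=True), seed=0
        )
        de_genes = {f"G{i}" for i in range(30)}
        assert len(set(pooled.index) & de_genes) >= 15  # the confound is real
        assert len(set(centred.index) & de_genes) <= 2  # and centring removes it

    def test_top_quantile_rule(self):
        rng = np.random.default_rng(11)
        genes = _gene_matrix(rng.uniform(0, 10, size=(50, 60)))
        x = pd.Series(rng.uniform(0, 10, 60), index=genes.sample_ids, name="M")
        cfg = MIConfig(target_rule="top-quantile", top_quantile=0.9, center_classes=False)
        called = candidate_targets(x, genes, cfg, seed=0)
        assert 0 < len(called) <= 6


class TestLinkMirnaPair:
    coll = GeneSetCollection(
        {
            "PX": ("", tuple(f"G{i}" for i in range(10))),
            "PY": ("", tuple(f"G{i}" for i in range(10, 20))),
        }
    )
    universe = [f"G{i}" for i in range(200)]

    def test_targets_covering_both_pathways_link(self):
        targets = [f"G{i}" for i in range(20)]
        link = link_mirna_pair(targets, ("PX", "PY"), self.coll, self.universe, mirna_id="M")
        assert link is not None
        assert link.p_x < 0.01 and link.p_y < 0.01
        assert link.pair_id == "PX|PY"

    def test_empty_targets_no_link(self):
        assert link_mirna_pair([], ("PX", "PY"), self.coll, self.universe) is None

    def test_one_sided_enrichment_no_link(self):
        targets = [f"G{i}" for i in range(10)]  # all inside PX only
        assert link_mirna_pair(targets, ("PX", "PY"), self.coll, self.universe) is None

    def test_targets_outside_universe_error(self):
        with pytest.raises(ValueError):
            link_mirna_pair(["NOPE"], ("PX", "PY"), self.coll, self.universe)


@pytest.fixture(scope="module")
def cohort():
    from pathcrosstalk.diffexpr import normalize_counts
    from pathcrosstalk.synthetic_data import simulate

    coll, genes, mirnas, truth = simulate(small_design(seed=17))
    norm = normalize_counts(genes)
    gene_log = norm.with_values(np.log2(norm.values + 1.0))
    return coll, gene_log, mirnas, truth


class TestRegulatorScan:
    config = MIConfig(n_perm=30, n_null_genes=80)

    def test_planted_regulator_found_with_both_p_small(self, cohort):
        coll, gene_log, mirnas, truth = cohort
        (pair,) = truth.crosstalk_pairs
        links = regulator_scan(
            mirnas, gene_log, [pair], coll, mi_config=self.config, seed=0
        )
        found = {(l.mirna_id, l.pair_id) for l in links}
        assert truth.regulator_links <= found
        for l in links:
            assert l.p_x < 0.01 and l.p_y < 0.01
            assert np.isfinite(l.logfc) and np.isfinite(l.fdr)

    def test_non_de_mirnas_are_filtered_out(self, cohort):
        coll, gene_log, mirnas, truth = cohort
        (pair,) = truth.crosstalk_pairs
        links = regulator_scan(
            mirnas, gene_log, [pair], coll, mi_config=self.config, seed=0
        )
        assert {l.mirna_id for l in links} <= set(truth.de_mirna_ids)

    def test_no_final_pairs_gives_empty(self, cohort):
        coll, gene_log, mirnas, _ = cohort
        assert regulator_scan(mirnas, gene_log, [], coll, mi_config=self.config) == []

    def test_sample_mismatch_errors(self, cohort):
        coll, gene_log, mirnas, truth = cohort
        (pair,) = truth.crosstalk_pairs
        shuffled = mirnas.subset_samples(list(reversed(mirnas.sample_ids)))
        with pytest.raises(ValueError, match="same samples"):
            regulator_scan(shuffled, gene_log, [pair], coll, mi_config=self.config)
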