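import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from pathcrosstalk import (
    DEConfig,
    ExpressionMatrix,
    bh_adjust,
    call_de,
    nb_exact_test,
    normalize_counts,
    size_factors,
    variance_quantile_filter,
)
from pathcrosstalk.diffexpr import DETable, _exact_nb_pvalue


def _matrix(values, n_case, n_control, prefix="G"):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"S{i}" for i in range(values.shape[1])],
    )
    labels = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=frame.columns
    )
    return ExpressionMatrix(frame, labels)


class TestVarianceFilter:
    def test_q0_removes_constant_rows_only(self):
        m = _matrix([[5, 5, 5, 5], [1, 2, 3, 4], [9, 1, 4, 2]], 2, 2)
        out = variance_quantile_filter(m, 0.0)
        assert out.feature_ids == ["G1", "G2"]

    def test_q0_identity_without_constants(self):
        m = _matrix([[1, 2, 3, 4], [9, 1, 4, 2]], 2, 2)
        out = variance_quantile_filter(m, 0.0)
        assert out.feature_ids == m.feature_ids

    def test_median_cut_keeps_about_half(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.gamma(2.0, 10.0, size=(1000, 10)), 5, 5)
        out = variance_quantile_filter(m, 0.5)
        assert abs(out.n_features - 500) <= 1

    def test_invalid_quantile_errors(self, toy_matrix):
        with pytest.raises(ValueError):
            variance_quantile_filter(toy_matrix, 1.0)


class TestNormalization:
    def test_scaled_columns_normalize_equal(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50.0, size=(100, 1)).astype(float)
        values = np.hstack([base, 2.0 * base, base, 2.0 * base])
        m = _matrix(values, 2, 2)
        norm = normalize_counts(m).values.to_numpy()
        np.testing.assert_allclose(norm[:, 0], norm[:, 1], rtol=1e-12)
        np.testing.assert_allclose(norm[:, 0], norm[:, 3], rtol=1e-12)

    def test_single_sample_scaled_to_cpm(self):
        values = pd.DataFrame({"S1": [10.0, 30.0, 60.0]}, index=["G0", "G1", "G2"])
        m = ExpressionMatrix(values, pd.Series(["case"], index=["S1"]))
        norm = normalize_counts(m).values
        assert norm["S1"].sum() == pytest.approx(1e6)
        np.testing.assert_allclose(
            (norm["S1"] / norm["S1"].iloc[0]).to_numpy(), [1.0, 3.0, 6.0]
        )

    def test_size_factors_recover_planted_library_inflation(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(20, 200, size=500)
        counts = rng.poisson(mu[:, None], size=(500, 6)).astype(float)
        counts[:, 3:] = rng.poisson(3.0 * mu[:, None], size=(500, 3))
        m = _matrix(counts, 3, 3)
        f = size_factors(m).to_numpy()
        ratio = f[3:].mean() / f[:3].mean()
        assert ratio == pytest.approx(3.0, rel=0.05)

    def test_all_zero_sample_errors_with_name(self):
        values = np.ones((3, 4))
        values[:, 2] = 0.0
        m = _matrix(values, 2, 2)
        with pytest.raises(ValueError, match="S2"):
            normalize_counts(m)


class TestBHAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04]
        )

    def test_equal_pvalues_are_fixed_point(self):
        np.testing.assert_array_equal(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == 0.37

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 51))
        # independent step-up oracle: explicit min over j >= i on sorted values
        order = np.argsort(p, kind="mergesort")
        m = len(p)
        sorted_p = p[order]
        expected_sorted = np.empty(m)
        for i in range(m):
            expected_sorted[i] = min(
                min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
            )
        expected = np.empty(m)
        expected[order] = expected_sorted
        np.testing.assert_array_equal(bh_adjust(p), expected)


def _binomial_probability_mass_p(z1, z2, n1, n2):
    """Independent oracle: conditional binomial exact test, probability-mass rule."""
    z = z1 + z2
    pmf = np.array([binom.pmf(u, z, n1 / (n1 + n2)) for u in range(z + 1)])
    return min(1.0, pmf[pmf <= pmf[z1] * (1 + 1e-9)].sum())


class TestExactTest:
    def test_identical_groups_give_null_result(self):
        values = np.tile([[10.0], [25.0], [40.0]], (1, 8))
        m = _matrix(values, 4, 4)
        table = nb_exact_test(m, DEConfig())
        np.testing.assert_allclose(table.frame["logfc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table.frame["pvalue"], 1.0)

    @pytest.mark.parametrize(
        "z1,z2,n1,n2",
        [(5, 10, 3, 3), (0, 12, 4, 4), (30, 12, 5, 3), (100, 60, 10, 10), (7, 7, 2, 6)],
    )
    def test_poisson_limit_matches_binomial_oracle(self, z1, z2, n1, n2):
        ours = _exact_nb_pvalue(z1, z2, n1, n2, phi=0.0)
        oracle = _binomial_probability_mass_p(z1, z2, n1, n2)
        assert ours == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("z1,z2,phi", [(4000, 2500, 0.05), (900, 5600, 0.2)])
    def test_windowed_large_total_matches_full_summation(self, z1, z2, phi):
        from scipy.special import gammaln, logsumexp

        n1 = n2 = 6
        r1, r2 = n1 / phi, n2 / phi
        z = z1 + z2
        u = np.arange(z + 1)
        lp = (
            gammaln(u + r1) - gammaln(u + 1) - gammaln(r1)
            + gammaln(z - u + r2) - gammaln(z - u + 1) - gammaln(r2)
        )
        lp -= logsumexp(lp)
        expected = np.exp(logsumexp(lp[lp <= lp[z1] + 1e-10]))
        assert _exact_nb_pvalue(z1, z2, n1, n2, phi) == pytest.approx(expected, rel=1e-6)

    def test_signed_logfc_monotone_in_case_counts(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(60.0, size=(40, 12)).astype(float)
        m = _matrix(counts, 6, 6)
        base = nb_exact_test(m, DEConfig()).frame["logfc"]
        for bump in (5.0, 50.0, 500.0):
            counts2 = counts.copy()
            counts2[7, :6] += bump
            m2 = _matrix(counts2, 6, 6)
            new = nb_exact_test(m2, DEConfig()).frame["logfc"]
            assert new.iloc[7] >= base.iloc[7] - 1e-9
            base = new
            counts = counts2

    def test_pooled_mom_mode_runs(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(40.0, size=(50, 8)).astype(float)
        m = _matrix(counts, 4, 4)
        table = nb_exact_test(m, DEConfig(dispersion_mode="pooled-MoM"))
        assert np.all((table.frame["pvalue"] > 0) & (table.frame["pvalue"] <= 1))

    def test_single_class_errors(self):
        values = np.ones((3, 4)) * 5
        frame = pd.DataFrame(values, index=["G0", "G1", "G2"],
                             columns=["S0", "S1", "S2", "S3"])
        m = ExpressionMatrix(frame, pd.Series(["case"] * 4, index=frame.columns))
        with pytest.raises(ValueError):
            nb_exact_test(m, DEConfig())


class TestCallDE:
    @pytest.mark.parametrize(
        "logfc,fdr,called",
        [(1.5, 0.005, True), (0.9, 0.001, False), (2.0, 0.02, False), (1.0, 0.005, False)],
    )
    def test_strict_thresholds(self, logfc, fdr, called):
        frame = pd.DataFrame(
            {"logfc": [logfc], "pvalue": [fdr / 2], "fdr": [fdr], "is_de": [False]},
            index=["G0"],
        )
        table = DETable(frame, 0.1, DEConfig())
        assert (len(call_de(table)) == 1) is called

    def test_sorted_by_fdr(self):
        frame = pd.DataFrame(
            {"logfc": [2.0, 3.0, -2.0], "pvalue": [1e-3, 1e-6, 1e-4],
             "fdr": [1e-2 / 2, 1e-5, 1e-3], "is_de": [True] * 3},
            index=["A", "B", "C"],
        )
        assert call_de(DETable(frame, 0.1, DEConfig())) == ["B", "C", "A"]


class TestEdgeRCrossCheck:
    def test_pvalues_track_edger_exact_test(self, tmp_path):
        """Independent route: edgeR's qCML common dispersion + exact test on
        the same counts should order features the same way."""
        rng = np.random.default_rng(8)
        mu = rng.uniform(20, 200, size=200)
        lfc = np.zeros(200)
        lfc[:20] = rng.choice([-2.0, 2.0], 20)
        r = 1 / 0.1
        case = rng.negative_binomial(r, r / (r + mu[:, None] * 2**lfc[:, None]), size=(200, 8))
        ctrl = rng.negative_binomial(r, r / (r + mu[:, None]), size=(200, 8))
        counts = np.hstack([case, ctrl]).astype(float)
        m = _matrix(counts, 8, 8)
        ours = nb_exact_test(m, DEConfig())

        counts_path = tmp_path / "counts.tsv"
        out_path = tmp_path / "edger.tsv"
        pd.DataFrame(counts, index=m.feature_ids, columns=m.sample_ids).to_csv(
            counts_path, sep="\t"
        )
        script = f"""
        suppressMessages(library(edgeR))
        x <- read.delim("{counts_path}", row.names=1)
        group <- factor(c(rep("case",8), rep("control",8)), levels=c("control","case"))
        y <- DGEList(counts=x, group=group)
        y <- calcNormFactors(y)
        y <- estimateCommonDisp(y)
        et <- exactTest(y)
        write.table(data.frame(feature=rownames(et$table), et$table, disp=y$common.dispersion),
                    "{out_path}", sep="\\t", quote=FALSE, row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t", index_col=0).loc[m.feature_ids]

        assert ours.dispersion == pytest.approx(float(ref["disp"].iloc[0]), rel=0.5)
        ours_lp = -np.log10(ours.frame["pvalue"] + 1e-300)
        ref_lp = -np.log10(ref["PValue"] + 1e-300)
        assert np.corrcoef(ours_lp, ref_lp)[0, 1] > 0.95
        assert np.corrcoef(ours.frame["logfc"], ref["logFC"])[0, 1] > 0.95
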