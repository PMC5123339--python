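"""Count-based differential expression for genes and miRNAs.

The pipeline's DE step follows the classic exact-test workflow for
negative-binomial counts: per-sample library-size equalisation, a common
dispersion estimated by conditional maximum likelihood on the equalised
pseudo-counts (qCML), a two-sided exact test on the per-group pseudo-sums,
Benjamini-Hochberg adjustment, and calling at |log2FC| > 1 and FDR < 0.01.

A variance-quantile pre-filter and a median-of-ratios normalisation (used for
fold-change estimation and for all downstream per-sample expression scales)
live here as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .io_formats import CASE, CONTROL, ExpressionMatrix

logger = logging.getLogger(__name__)

_POISSON_PHI = 1e-8  # below this the exact test uses its conditional-binomial limit


@dataclass
class DEConfig:
    """Thresholds and estimation choices for one DE contrast.

    ``lfc_threshold`` is on the log2 scale; calling is strict:
    |logFC| > lfc_threshold AND fdr < fdr_threshold.  For miRNA contrasts the
    convention is ``lfc_threshold = 0`` (FDR-only calling).
    """

    variance_quantile: float = 0.25
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.01
    dispersion_mode: str = "common-qCML"  # or "pooled-MoM"
    pseudo_count: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.variance_quantile < 1.0):
            raise ValueError("variance_quantile must be in [0, 1)")
        if self.lfc_threshold < 0 or not (0 < self.fdr_threshold <= 1):
            raise ValueError("invalid thresholds")
        if self.dispersion_mode not in ("common-qCML", "pooled-MoM"):
            raise ValueError(f"unknown dispersion_mode {self.dispersion_mode!r}")


@dataclass
class DETable:
    """Per-feature DE results: logFC, p, BH-adjusted p, and the called flag."""

    frame: pd.DataFrame  # columns: logfc, pvalue, fdr, is_de
    dispersion: float
    config: DEConfig

    @property
    def loc(self):
        return self.frame.loc


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def variance_quantile_filter(matrix: ExpressionMatrix, q: float) -> ExpressionMatrix:
    """Keep features whose across-sample variance is strictly above the
    q-th empirical quantile of all feature variances (q=0: drop constants)."""
    if not (0.0 <= q < 1.0):
        raise ValueError("q must be in [0, 1)")
    if matrix.n_features == 0:
        raise ValueError("empty matrix")
    variances = matrix.values.var(axis=1, ddof=1)
    threshold = 0.0 if q == 0.0 else float(np.quantile(variances.to_numpy(), q))
    keep = variances > threshold
    dropped = int((~keep).sum())
    if dropped:
        logger.info("variance filter (q=%.3g) dropped %d/%d features", q, dropped, len(keep))
    return ExpressionMatrix(matrix.values.loc[keep], matrix.class_labels)


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors, scaled to geometric mean 1.

    Computed on features with a strictly positive geometric mean; if no such
    feature exists, falls back to library-size factors.
    """
    counts = matrix.values.to_numpy(dtype=float)
    libs = counts.sum(axis=0)
    zero = np.flatnonzero(libs == 0)
    if zero.size:
        raise ValueError(f"all-zero sample: {matrix.sample_ids[zero[0]]!r}")
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        log_geo = logc.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logc - log_geo, axis=0))
    else:
        logger.warning("no feature with all-positive counts; using library-size factors")
        factors = libs
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million on median-of-ratios effective library sizes.

    Each sample is divided by its size factor and globally rescaled so the
    mean adjusted library equals one million; the output is the "normalized
    expression" scale used by every downstream per-sample statistic.
    """
    factors = size_factors(matrix).to_numpy()
    counts = matrix.values.to_numpy(dtype=float)
    adjusted = counts / factors[None, :]
    mean_lib = adjusted.sum(axis=0).mean()
    scaled = adjusted * (1e6 / mean_lib)
    return matrix.with_values(
        pd.DataFrame(scaled, index=matrix.feature_ids, columns=matrix.sample_ids)
    )


# ---------------------------------------------------------------------------
# qCML dispersion + exact test
# ---------------------------------------------------------------------------

def _pseudo_counts(counts: np.ndarray) -> np.ndarray:
    """Equalise library sizes: scale every sample to the geometric-mean library."""
    libs = counts.sum(axis=0)
    if (libs == 0).any():
        raise ValueError("all-zero sample")
    target = np.exp(np.mean(np.log(libs)))
    return counts * (target / libs)[None, :]


def _conditional_loglik(pseudo: np.ndarray, groups: list[np.ndarray], phi: float) -> float:
    """Common-dispersion conditional log-likelihood over all features/groups
    (terms independent of the dispersion are dropped)."""
    total = 0.0
    for cols in groups:
        y = pseudo[:, cols]
        n = len(cols)
        z = y.sum(axis=1)
        if phi <= _POISSON_PHI:
            total += float(np.sum(-z * np.log(n)))
            continue
        r = 1.0 / phi
        total += float(
            np.sum(gammaln(y + r)) - y.shape[0] * n * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    pseudo: np.ndarray, groups: list[np.ndarray], grid: np.ndarray | None = None
) -> float:
    """qCML common dispersion: maximise the conditional likelihood of the
    per-group pseudo-counts over a dispersion grid."""
    informative = pseudo.sum(axis=1) > 0
    pseudo = pseudo[informative]
    if pseudo.shape[0] == 0:
        return 0.0
    if grid is None:
        grid = np.concatenate([[0.0], np.logspace(-4, 1, 51)])
    ll = np.array([_conditional_loglik(pseudo, groups, phi) for phi in grid])
    return float(grid[int(np.argmax(ll))])


def _pooled_mom_dispersion(pseudo: np.ndarray, groups: list[np.ndarray]) -> float:
    """Pooled method-of-moments dispersion: median over features of
    max(0, (s^2 - mu) / mu^2) with within-group moments pooled."""
    num = np.zeros(pseudo.shape[0])
    mu = np.zeros(pseudo.shape[0])
    dof = 0
    for cols in groups:
        y = pseudo[:, cols]
        m = y.mean(axis=1)
        num += ((y - m[:, None]) ** 2).sum(axis=1)
        mu += m * len(cols)
        dof += len(cols) - 1
    mu = mu / sum(len(c) for c in groups)
    s2 = num / max(dof, 1)
    keep = mu > 0
    if not keep.any():
        return 0.0
    phis = np.maximum(0.0, (s2[keep] - mu[keep]) / mu[keep] ** 2)
    return float(np.median(phis))


def _exact_nb_pvalue(z1: int, z2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact test of the split of z1+z2 between two groups of equal
    library size, by the probability-mass rule (sum all outcomes at most as
    probable as the observed one).

    The null split follows the negative-binomial convolution conditional
    (a negative hypergeometric; the conditional binomial in the Poisson
    limit).  For large totals only the unimodal region with pmf above the
    observed one is evaluated: p = 1 - P(pmf > pmf_obs).
    """
    z = z1 + z2
    if z == 0:
        return 1.0
    tol = 1e-10
    if phi <= _POISSON_PHI:
        frac = n1 / (n1 + n2)

        def lpmf(u: np.ndarray) -> np.ndarray:
            return binom.logpmf(u, z, frac)

        mode = int(round(z * frac))
    else:
        r1, r2 = n1 / phi, n2 / phi
        # Vandermonde convolution gives the normalising constant in closed form
        log_c = gammaln(z + r1 + r2) - gammaln(z + 1) - gammaln(r1 + r2)

        def lpmf(u: np.ndarray) -> np.ndarray:
            return (
                gammaln(u + r1) - gammaln(u + 1) - gammaln(r1)
                + gammaln(z - u + r2) - gammaln(z - u + 1) - gammaln(r2)
                - log_c
            )

        mode = int(round(z * r1 / (r1 + r2)))

    if z <= 2048:
        lp = lpmf(np.arange(z + 1))
        keep = lp <= lp[z1] + tol
        return float(min(1.0, np.exp(logsumexp(lp[keep]))))

    obs = float(lpmf(np.array([z1]))[0])
    mode = min(max(mode, 0), z)
    if float(lpmf(np.array([mode]))[0]) <= obs + tol:
        return 1.0
    # the pmf is unimodal, so {pmf <= pmf_obs} is two tails; accumulate each
    # tail outward from the crossing point until its mass stops growing
    chunk = 2048
    p_total = 0.0

    def tail(start: int, step: int) -> float:
        acc = 0.0
        crossed = False
        u = start
        while 0 <= u <= z:
            if step > 0:
                us = np.arange(u, min(u + chunk, z + 1))
            else:
                us = np.arange(max(0, u - chunk + 1), u + 1)
            lp = lpmf(us)
            kept = lp <= obs + tol
            add = float(np.exp(lp[kept]).sum())
            acc += add
            if crossed and add <= 1e-18 * max(acc, 1e-300):
                break
            if kept.any():
                crossed = True
            u += step * chunk
        return acc

    p_total = tail(mode, +1) + tail(mode - 1, -1)
    return float(min(1.0, p_total))


def nb_exact_test(matrix: ExpressionMatrix, config: DEConfig | None = None) -> DETable:
    """Common-dispersion NB exact test of case vs control for every feature.

    Library sizes are equalised to the geometric-mean library, a common
    dispersion is estimated by qCML (or pooled method-of-moments), and each
    feature's per-group pseudo-sums are compared with a two-sided exact test.
    logFC is log2 of the ratio of normalized group means with a pseudo-count
    of ``config.pseudo_count``.
    """
    config = config or DEConfig()
    case_cols = np.array(
        [i for i, s in enumerate(matrix.sample_ids) if matrix.class_labels[s] == CASE]
    )
    control_cols = np.array(
        [i for i, s in enumerate(matrix.sample_ids) if matrix.class_labels[s] == CONTROL]
    )
    if len(case_cols) == 0 or len(control_cols) == 0:
        raise ValueError("both classes must be present")
    if len(case_cols) < 2 or len(control_cols) < 2:
        raise ValueError("both classes need >= 2 samples")

    counts = matrix.values.to_numpy(dtype=float)
    pseudo = _pseudo_counts(counts)
    groups = [case_cols, control_cols]
    if config.dispersion_mode == "common-qCML":
        phi = estimate_common_dispersion(pseudo, groups)
    else:
        phi = _pooled_mom_dispersion(pseudo, groups)

    z1 = np.rint(pseudo[:, case_cols].sum(axis=1)).astype(np.int64)
    z2 = np.rint(pseudo[:, control_cols].sum(axis=1)).astype(np.int64)
    n1, n2 = len(case_cols), len(control_cols)
    pvalues = np.array(
        [_exact_nb_pvalue(int(a), int(b), n1, n2, phi) for a, b in zip(z1, z2)]
    )

    norm = normalize_counts(matrix).values.to_numpy()
    mc = norm[:, case_cols].mean(axis=1)
    mn = norm[:, control_cols].mean(axis=1)
    pc = config.pseudo_count
    logfc = np.log2((mc + pc) / (mn + pc))

    fdr = bh_adjust(pvalues)
    is_de = (np.abs(logfc) > config.lfc_threshold) & (fdr < config.fdr_threshold)
    frame = pd.DataFrame(
        {"logfc": logfc, "pvalue": pvalues, "fdr": fdr, "is_de": is_de},
        index=matrix.feature_ids,
    )
    return DETable(frame, phi, config)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def call_de(table: DETable, config: DEConfig | None = None) -> list[str]:
    """Features passing both strict thresholds, sorted by ascending FDR."""
    config = config or table.config
    frame = table.frame
    mask = (frame["logfc"].abs() > config.lfc_threshold) & (
        frame["fdr"] < config.fdr_threshold
    )
    hits = frame.loc[mask].sort_values(
        by=["fdr", "pvalue"], kind="mergesort"
    )
    return list(hits.index)
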