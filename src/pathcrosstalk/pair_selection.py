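"""Bootstrap selection of discriminative pathway pairs.

Each bootstrap balances the two classes by downsampling, splits 60/40 into
train/test, recomputes DE and pathway enrichment on the training samples,
builds the interaction-score matrix over pairs of enriched pathways, scores
every pair with a stratified k-fold cross-validated random forest (AUC of
pooled out-of-fold case probabilities), keeps the top pairs, and validates
them on the held-out samples.  Across bootstraps, pairs are ranked by how
often they reach a per-bootstrap top list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .crosstalk import build_is_matrix
from .diffexpr import DEConfig, call_de, nb_exact_test
from .enrichment import enrich_pathways
from .io_formats import CASE, CONTROL, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    """Random-forest and bootstrap-loop settings.

    Defaults follow the study conventions: 500 trees, mtry = sqrt(p) input
    variables per split, 10-fold CV (5 when the per-class training count
    falls below ``small_cohort_threshold``), a 60/40 balanced Monte-Carlo
    split, 50 bootstraps, top-10 pairs per bootstrap.
    """

    n_trees: int = 500
    k_folds: int = 10
    small_k: int = 5
    small_cohort_threshold: int = 30
    train_fraction: float = 0.6
    n_bootstraps: int = 50
    top_n: int = 10
    use_matrix_importance: bool = False
    test_internal_cv: bool = False

    def __post_init__(self) -> None:
        if self.k_folds < 2 or self.small_k < 2:
            raise ValueError("k_folds must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_bootstraps < 1 or self.top_n < 1 or self.n_trees < 1:
            raise ValueError("counts must be positive")

    def effective_k(self, per_class_train: int) -> int:
        return self.small_k if per_class_train < self.small_cohort_threshold else self.k_folds


@dataclass
class BootstrapResult:
    """Everything one bootstrap produced."""

    index: int
    train_ids: list[str]
    test_ids: list[str]
    de_genes: list[str]
    de_table: pd.DataFrame
    enriched: list[tuple[str, float]]
    cv_auc: dict[str, float]
    top_pairs: list[str]
    test_auc: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class FrequencyRanking:
    """Pair appearance counts across bootstraps with mean AUCs."""

    counts: dict[str, int]
    mean_cv_auc: dict[str, float]
    mean_test_auc: dict[str, float]
    n_bootstraps: int
    top_n: int
    top: list[str] = field(default_factory=list)

    def ordered_pairs(self) -> list[str]:
        """All observed pairs: descending count, ties by descending mean
        CV-AUC, then pair name."""
        return sorted(
            self.counts,
            key=lambda p: (-self.counts[p], -self.mean_cv_auc[p], p),
        )

    def as_frame(self) -> pd.DataFrame:
        pairs = self.ordered_pairs()
        return pd.DataFrame(
            {
                "pair": pairs,
                "count": [self.counts[p] for p in pairs],
                "n_boots": self.n_bootstraps,
                "mean_cv_auc": [self.mean_cv_auc[p] for p in pairs],
                "mean_test_auc": [self.mean_test_auc[p] for p in pairs],
            }
        ).set_index("pair")


def _mtry(p: int, rule: str = "sqrt") -> int:
    return max(1, int(np.sqrt(p)))


def _as_int_seed(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0] & 0x7FFFFFFF)
    return int(seed) & 0x7FFFFFFF


def balanced_split(
    labels: pd.Series, train_fraction: float = 0.6, seed: int | np.random.SeedSequence = 0
) -> tuple[list[str], list[str]]:
    """Class-balanced Monte-Carlo split.

    The majority class is randomly downsampled to the minority size n_min;
    each class then contributes floor(train_fraction * n_min) training
    samples and the remainder to the test set, so both parts hold equal
    class counts and are disjoint.
    """
    rng = np.random.default_rng(seed)
    case_ids = list(labels.index[labels == CASE])
    control_ids = list(labels.index[labels == CONTROL])
    for name, ids in ((CASE, case_ids), (CONTROL, control_ids)):
        if len(ids) < 5:
            raise ValueError(f"class {name!r} has fewer than 5 samples")
    n_min = min(len(case_ids), len(control_ids))
    n_train = int(np.floor(train_fraction * n_min))
    if n_train < 1 or n_train >= n_min:
        raise ValueError("train_fraction leaves an empty train or test part")
    train: list[str] = []
    test: list[str] = []
    for ids in (case_ids, control_ids):
        picked = list(rng.permutation(ids)[:n_min])
        train.extend(picked[:n_train])
        test.extend(picked[n_train:n_min])
    return sorted(train), sorted(test)


def pair_cv_auc(
    is_column,
    labels,
    config: ClassifierConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    k: int | None = None,
) -> float:
    """Stratified k-fold CV AUC of a random forest on one IS column.

    The score is the AUC of pooled out-of-fold case-class probabilities;
    a single-feature pair uses mtry = 1.
    """
    config = config or ClassifierConfig()
    x = np.asarray(is_column, dtype=float)
    y = np.asarray([lab == CASE for lab in labels])
    if not np.isfinite(x).all():
        raise ValueError("IS column contains non-finite values")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    k = k or config.k_folds
    ss = np.random.SeedSequence(_as_int_seed(seed))
    fold_seeds = ss.generate_state(k + 1)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[0] & 0x7FFFFFFF))
    X = x.reshape(-1, 1)
    scores = np.empty(len(y))
    for i, (tr, te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=_mtry(1),
            random_state=int(fold_seeds[i + 1] & 0x7FFFFFFF),
            n_jobs=1,
        )
        rf.fit(X[tr], y[tr])
        scores[te] = rf.predict_proba(X[te])[:, list(rf.classes_).index(True)]
    return float(roc_auc_score(y, scores))


def rf_holdout_auc(
    train_values,
    train_labels,
    test_values,
    test_labels,
    config: ClassifierConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Fit a forest on the full training column, score the held-out rows."""
    config = config or ClassifierConfig()
    ytr = np.asarray([lab == CASE for lab in train_labels])
    yte = np.asarray([lab == CASE for lab in test_labels])
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=_mtry(1),
        random_state=_as_int_seed(seed),
        n_jobs=1,
    )
    rf.fit(np.asarray(train_values, dtype=float).reshape(-1, 1), ytr)
    scores = rf.predict_proba(np.asarray(test_values, dtype=float).reshape(-1, 1))
    return float(roc_auc_score(yte, scores[:, list(rf.classes_).index(True)]))


def _empty_result(index: int, train: list[str], test: list[str], de_genes, de_frame, enriched) -> BootstrapResult:
    return BootstrapResult(
        index=index,
        train_ids=train,
        test_ids=test,
        de_genes=de_genes,
        de_table=de_frame,
        enriched=enriched,
        cv_auc={},
        top_pairs=[],
        test_auc={},
    )


def bootstrap_once(
    gene_counts: ExpressionMatrix,
    collection: GeneSetCollection,
    de_config: DEConfig,
    clf_config: ClassifierConfig,
    boot_seed: int,
    enrichment_alpha: float = 0.01,
    expr_norm: ExpressionMatrix | None = None,
    index: int = 0,
) -> BootstrapResult:
    """One bootstrap: split, DE on train, enrichment, IS matrix, pair AUCs.

    ``gene_counts`` are raw (filtered) counts; ``expr_norm`` is the
    normalized matrix used for the IS statistics (computed from
    ``gene_counts`` if not supplied).
    """
    from .diffexpr import normalize_counts  # local import avoids cycle at module load

    ss = np.random.SeedSequence(_as_int_seed(boot_seed))
    split_ss, cv_ss, test_ss = ss.spawn(3)

    train, test = balanced_split(gene_counts.class_labels, clf_config.train_fraction, split_ss)

    de_table = nb_exact_test(gene_counts.subset_samples(train), de_config)
    de_genes = call_de(de_table)

    enr = enrich_pathways(de_genes, collection, gene_counts.feature_ids, enrichment_alpha)
    enriched = [(r.pathway_name, r.p_value) for r in enr if r.is_enriched]
    enriched_names = [name for name, _ in enriched]

    if len(enriched_names) < 2:
        logger.warning("bootstrap %d: <2 enriched pathways, empty result", index)
        return _empty_result(index, train, test, de_genes, de_table.frame, enriched)

    if expr_norm is None:
        expr_norm = normalize_counts(gene_counts)
    ism = build_is_matrix(expr_norm.subset_samples(train + test), enriched_names, collection)

    per_class_train = len(train) // 2
    k = clf_config.effective_k(per_class_train)
    train_rows = ism.values.loc[train]
    test_rows = ism.values.loc[test]
    train_labels = ism.class_labels.loc[train]
    test_labels = ism.class_labels.loc[test]

    pair_ids = ism.pair_ids
    cv_seeds = cv_ss.spawn(len(pair_ids))
    if clf_config.use_matrix_importance:
        # alternative ranking: one forest on the whole IS matrix, pairs
        # ordered by variable importance
        rf = RandomForestClassifier(
            n_estimators=clf_config.n_trees,
            max_features=_mtry(len(pair_ids)),
            random_state=_as_int_seed(cv_seeds[0]),
            n_jobs=1,
        )
        rf.fit(train_rows.to_numpy(), np.asarray([l == CASE for l in train_labels]))
        order = sorted(
            zip(pair_ids, rf.feature_importances_), key=lambda t: (-t[1], t[0])
        )
        top_pairs = [p for p, _ in order[: clf_config.top_n]]
        cv_auc = {
            p: pair_cv_auc(train_rows[p], train_labels, clf_config, cv_seeds[i], k=k)
            for i, p in enumerate(top_pairs)
        }
    else:
        cv_auc = {
            p: pair_cv_auc(train_rows[p], train_labels, clf_config, cv_seeds[i], k=k)
            for i, p in enumerate(pair_ids)
        }
        ranked = sorted(cv_auc, key=lambda p: (-cv_auc[p], p))
        top_pairs = ranked[: clf_config.top_n]
        if len(ranked) < clf_config.top_n:
            logger.info(
                "bootstrap %d: only %d pairs available (< top_n=%d)",
                index, len(ranked), clf_config.top_n,
            )

    test_seeds = test_ss.spawn(len(top_pairs))
    test_auc: dict[str, float] = {}
    for i, p in enumerate(top_pairs):
        if clf_config.test_internal_cv:
            test_auc[p] = pair_cv_auc(
                test_rows[p], test_labels, clf_config, test_seeds[i], k=clf_config.small_k
            )
        else:
            test_auc[p] = rf_holdout_auc(
                train_rows[p], train_labels, test_rows[p], test_labels, clf_config, test_seeds[i]
            )

    return BootstrapResult(
        index=index,
        train_ids=train,
        test_ids=test,
        de_genes=de_genes,
        de_table=de_table.frame,
        enriched=enriched,
        cv_auc=cv_auc,
        top_pairs=top_pairs,
        test_auc=test_auc,
    )


def run_bootstraps(
    gene_counts: ExpressionMatrix,
    collection: GeneSetCollection,
    de_config: DEConfig,
    clf_config: ClassifierConfig,
    seed: int = 0,
    enrichment_alpha: float = 0.01,
    expr_norm: ExpressionMatrix | None = None,
) -> list[BootstrapResult]:
    """Run ``clf_config.n_bootstraps`` independent bootstraps from seed
    substreams; output order and content equal sequential execution."""
    from .diffexpr import normalize_counts

    if expr_norm is None:
        expr_norm = normalize_counts(gene_counts)
    boot_seeds = np.random.SeedSequence(seed).spawn(clf_config.n_bootstraps)
    results = []
    for i, bss in enumerate(boot_seeds):
        results.append(
            bootstrap_once(
                gene_counts,
                collection,
                de_config,
                clf_config,
                _as_int_seed(bss),
                enrichment_alpha=enrichment_alpha,
                expr_norm=expr_norm,
                index=i,
            )
        )
        logger.info(
            "bootstrap %d/%d: %d DE genes, %d enriched pathways, best CV-AUC %.3f",
            i + 1, clf_config.n_bootstraps, len(results[-1].de_genes),
            len(results[-1].enriched),
            max(results[-1].cv_auc.values(), default=float("nan")),
        )
    return results


def frequency_rank(results: Sequence[BootstrapResult], top_n: int = 10) -> FrequencyRanking:
    """Rank pairs by how often they appear in per-bootstrap top lists.

    The final list keeps the ``top_n`` most frequent pairs, ties broken by
    higher mean CV-AUC, then lexicographic pair name.
    """
    if len(results) == 0:
        raise ValueError("no bootstrap results")
    counts: dict[str, int] = {}
    cv_lists: dict[str, list[float]] = {}
    test_lists: dict[str, list[float]] = {}
    for res in results:
        for pair in res.top_pairs:
            counts[pair] = counts.get(pair, 0) + 1
            cv_lists.setdefault(pair, []).append(res.cv_auc[pair])
            test_lists.setdefault(pair, []).append(res.test_auc[pair])
    mean_cv = {p: float(np.mean(v)) for p, v in cv_lists.items()}
    mean_test = {p: float(np.mean(v)) for p, v in test_lists.items()}
    ranking = FrequencyRanking(
        counts=counts,
        mean_cv_auc=mean_cv,
        mean_test_auc=mean_test,
        n_bootstraps=len(results),
        top_n=top_n,
    )
    ranking.top = ranking.ordered_pairs()[:top_n]
    return ranking
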