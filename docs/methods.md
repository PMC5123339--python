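# Methods

`pathcrosstalk` identifies pairs of gene pathways whose coordinated
expression discriminates a tumour (case) cohort from normal (control)
samples, and miRNAs that plausibly regulate both members of such a pair.
This note documents the statistical procedure, its tunable parameters, the
synthetic-data model used to validate every stage, and the numerical and
design choices that were genuinely open.

## The procedure

The analysis runs on a gene count matrix and a matched miRNA count matrix
(features x samples, identical samples) with a binary class label per
sample, plus a pathway collection in GMT format.

1. **Variance filter.** Features whose across-sample variance falls at or
   below the `variance_quantile` (default q = 0.25) of all feature
   variances are removed; at q = 0 only constant features drop.
2. **Normalisation.** Median-of-ratios size factors (computed on features
   with an all-positive count profile) rescale each sample; columns are
   globally scaled to counts-per-million. All per-sample expression
   statistics downstream use log2(normalized + 1), which stabilises the
   spread term of the interaction score.
3. **Balanced bootstrap loop** (`n_bootstraps`, default 50). Each bootstrap:
   - downsamples the majority class to the minority size and splits each
     class 60/40 into train/test (`train_fraction` = 0.6), so both parts
     hold equal class counts;
   - calls differential expression on the *training* counts: common
     negative-binomial dispersion by quantile-adjusted conditional maximum
     likelihood (qCML), a two-sided exact test on per-group pseudo-sums,
     Benjamini-Hochberg adjustment, and strict calling at |log2FC| > 1 and
     FDR < 0.01;
   - tests each pathway for over-representation of the DE list with the
     one-sided hypergeometric tail against the measured-gene universe;
     pathways with raw p < 0.01 are enriched (no multiplicity correction at
     this stage — the raw-p rule is the procedure's convention);
   - builds the interaction-score matrix: for each unordered pair (X, Y) of
     enriched pathways and each sample, IS = |M_X − M_Y| / (S_X + S_Y),
     where M and S are the mean and (n−1)-denominator standard deviation of
     the pathway's measured genes in that sample. IS near 0 means maximal
     cross-talk. When S_X + S_Y = 0 the score is 0 if the means agree and
     an infinity sentinel otherwise; sentinels are capped at 10x the finite
     column maximum so the classifier input stays finite while order is
     preserved (huge IS = minimal cross-talk);
   - scores every pair with a stratified k-fold cross-validated random
     forest on the single IS column (`n_trees` = 500, mtry = sqrt(p), k =
     10, or k = 5 when the per-class training count falls below 30); the
     pair's score is the AUC of pooled out-of-fold case-class vote
     fractions; the top 10 pairs per bootstrap are re-scored on the
     held-out samples with a forest fit on the full training rows.
4. **Frequency ranking.** Pairs are ranked by how often they appear in
   per-bootstrap top lists; ties break by higher mean CV-AUC, then pair
   name. The final list keeps the `top_n` = 10 most frequent pairs.
5. **Regulator scan.** miRNAs that are differentially expressed (FDR < 0.01;
   no fold-change cut for miRNAs — the miRNA calling rule is configurable
   and defaults to FDR-only) are tested against every final pair: candidate
   targets are genes whose Kraskov–Stögbauer–Grassberger (KSG, variant 1,
   k = 3) mutual information with the miRNA beats a per-miRNA permutation
   null (profiles shuffled `n_perm` = 100 times, null MIs pooled, empirical
   p BH-adjusted at alpha = 0.05). A miRNA links to a pair when its targets
   are hypergeometrically enriched at p < 0.01 in *both* pathways.
6. **Network.** Final pairs become pathway–pathway edges (frequency, mean
   AUCs); each regulator link contributes two miRNA–pathway edges (each
   carrying that pathway's enrichment p), exported as GraphML.

## Key modelling choices

- **qCML dispersion.** Library sizes are equalised by scaling every sample
  to the geometric-mean library (the Poisson-limit approximation of
  quantile adjustment), then a single common dispersion maximises the
  conditional likelihood of the per-group pseudo-counts over a grid
  (0 and 51 log-spaced values in [1e-4, 10]). No tagwise or trended
  shrinkage. A pooled method-of-moments estimate is available for inputs
  too small for the grid search to be meaningful.
- **Exact test.** Conditional on a feature's total pseudo-sum, the case
  share follows the negative-binomial convolution conditional (a negative
  hypergeometric; conditional binomial in the Poisson limit). The
  two-sided p sums all outcomes at most as probable as the observed one.
  For large totals only the unimodal region around the mode is evaluated
  and the two kept tails are accumulated directly, avoiding 1 − S
  cancellation. Pseudo-sums are rounded to integers.
- **logFC.** log2 of the ratio of normalized group means with a
  pseudo-count of 0.5 on each side, so fold changes are finite and shrink
  gently at low counts.
- **Enrichment universe.** The genes surviving the variance filter (the
  measured background), not the whole genome; configurable. Pathways with
  fewer than two universe genes are dropped — they could never yield a
  defined IS spread.
- **IS rows.** Both case and control samples: the classifier needs rows of
  both classes even though the score is described per tumour sample.
  Genes shared by both pathways of a pair contribute to both means; a flag
  excludes them instead.
- **Per-pair classifiers.** AUC is computed per pair (single-feature
  forest), which yields the per-pair, per-bootstrap AUC values the ranking
  consumes. Ranking by whole-matrix forest variable importance is offered
  behind `use_matrix_importance`.
- **Test-set validation** refits the forest on the full training rows of
  each top pair and scores the held-out rows. Running CV *inside* the test
  set is statistically odd but available behind `test_internal_cv`.
- **MI on within-class-centred values.** Candidate-target MI is computed on
  log2(normalized + 1) values with each feature's class mean removed
  (configurable). Without centring, any differentially expressed miRNA
  shares class-driven mutual information with every differentially
  expressed gene, so target lists collapse onto the DE list and every DE
  miRNA links to every pair. Centring restricts target calling to
  per-sample covariation, which is the signal a regulator actually leaves.
  The separate DE filter on the miRNA itself is unaffected.
- **MI target threshold.** How MI values become a target list is the least
  constrained step of the procedure; the default permutation-FDR rule is a
  calibrated choice, and a fixed top-quantile rule is provided as an
  alternative (`target_rule="top-quantile"`).
- **Tie-breaking jitter.** Count data produce exact ties that break k-NN
  neighbourhood counting; a deterministic jitter (seeded from a CRC of the
  feature ID, amplitude 1e-10 of the value range) is added before
  estimation, so results are reproducible across runs and platforms.
- **Determinism.** One global seed drives a documented hierarchy of named
  substreams (per bootstrap, per pair, per miRNA). Independent bootstraps
  may run concurrently in principle, but execution is sequential and output
  equals sequential order. Two runs with the same config and seed produce
  byte-identical output files.

## The synthetic cohort

`synthetic_data` generates the validation cohort; its defaults *are* the
bundled demonstration conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` / `n_mirnas` | 500 / 50 | features after filtering, desk scale |
| `n_case` / `n_control` | 60 / 60 | balanced two-class cohort |
| `n_pathways`, sizes | 20, 15–25 | GMT-style sets, 10% overlap between neighbours |
| `baseline_mean_range` | 50–150 | uniform per-feature expected counts |
| `dispersion` | 0.1 | common NB dispersion, var = mu + 0.1 mu^2 |
| `de_fraction`, `de_logfc` | 0.05, 2.0 | scattered planted DE, random signs |
| `crosstalk_pairs` | 3 pairs, gap 1.2 | planted cross-talk (below) |
| `decoy_pathways` | 2 | enriched but unshifted competitors |
| `pathway_de_fraction/logfc` | 0.75, 1.8 | balanced-sign DE inside enrichable pathways |
| `regulators` | 2, rho 0.8, 6 targets/pathway | latent-factor coupling (below) |

**Cross-talk planting.** The score only reacts to a between-class change in
the mean gap relative to the spreads, so the minimal generative mechanism
is a class-specific shift of pathway means. Each planted pair receives a
symmetric +-gap/2 shift on the log2 means of its two pathways — additive on
the scale where M is computed — in the direction that moves the two pathway
means further apart. Both halves matter: a one-sided shift would make every
pair containing the shifted pathway equally discriminative, leaving the
planted pair unrecoverable in principle; and the apart-moving direction
prevents the |.| folding of the numerator from cancelling the planted gap.
Pathways in planted pairs and decoys also receive balanced-sign DE genes
(half up, half down) so they are reliably *enriched* inside each bootstrap
without moving their mean level; the spread inflation this causes in case
samples applies to planted and decoy pathways alike.

**Regulator planting.** A per-sample latent factor h ~ N(0,1) multiplies the
regulator miRNA's mean by 2^(a·h) and each target's mean by 2^(−a·h)
(negative coupling by default; MI detection is sign-agnostic). The
coefficient a = sigma_n * sqrt(rho/(1−rho)) is chosen so the log-scale
correlation with a target is approximately rho, with sigma_n the typical
log2 noise sd at the baseline mean. Targets are reserved among genes
without planted class effects before pathway-DE planting, because a class
shift on the target (or the miRNA) mixes between-class and within-class
correlation components of opposite sign and dilutes the planted coupling.
Regulator miRNAs are additionally planted DE so the final filter keeps
them.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: realistic library-size variation, batch
effects, gene–gene correlation beyond the planted latent factors,
sequence-based miRNA targeting, or any subtype biology. The cohort
validates the *machinery* (calibration, ranking, recovery of planted
structure), not biological conclusions.

## Problem sizes used in tests and the acceptance script

The statistical rules are identical everywhere; only problem sizes are
scaled for the bundled demonstration: 10 bootstraps, 10-tree forests with
3-fold CV, 30 permutations pooled over 100 null genes for the MI null
(package defaults remain 50 bootstraps, 500 trees, 10-fold, 100
permutations). Reduced forests tie more out-of-fold scores and bias the
midrank AUC slightly low, which affects none of the rank-based selection;
the calibration check against the Gaussian ideal-observer AUC therefore
uses the full 500-tree forest. DE calibration uses 2000-gene null and
1000-gene planted cohorts; the KSG closed-form check uses n = 5000.

## Known limitations

- The common-dispersion qCML uses linear library equalisation, which is
  exact only in the Poisson limit; with strongly unequal libraries the
  exact-test calibration degrades (an edgeR cross-check guards the regime
  used here).
- Enrichment p-values are intentionally uncorrected across pathways,
  matching the procedure's raw p < 0.01 rule; with many pathways the
  enriched set contains false positives by construction.
- The IS treats a pathway as a bag of genes; no topology, signs, or
  gene–gene structure inside a pathway.
- Permutation-null MI p-values are bounded below by 1/(n_perm * n_null + 1);
  very small target sets on very small sample counts are undetectable.
- With heavy pathway overlap the same genes drive both members of a pair,
  and IS gaps lose interpretability; the generator keeps overlap at 10%.
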