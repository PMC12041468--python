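# Methods

This note documents the models, algorithms and parameter choices behind
`stromamatrix`, and what the synthetic-data tests do and do not demonstrate
about real data.

## TMT proteomics

**Reference-channel model.** Each TMT batch carries three reference channels
holding the same pooled control labeled at a 0.5 : 1 : 2 ratio. On the log2
scale the per-protein ratios 131N/131C, 131C/130N and 131N/130N are then
Gaussian around 1, 1 and 2; deviations measure technical variance.
`reference_ratio_qc` standardizes each ratio against its batch median and
sample standard deviation, converts to two-sided normal p-values, and flags
outliers by Benjamini–Hochberg at 0.05 across all three ratio vectors of a
batch jointly. This reproduces a "multidimensional significance" style
truncation as an explicit, formula-level rule (the original is a GUI tool
whose exact formula is not published); the flag is applied at the protein-row
level of the input table.

**Normalization.** Step 1 (systematic bias): log2-transform, subtract each
column's median, add back the mean of the original column medians, and
exponentiate — afterwards all column medians are equal on the log scale.
Step 2 (inter-sample): divide each protein by its value in a designated
reference column and multiply by that column's average normalized intensity.
The "average" is taken as the scalar mean over proteins (the per-protein
alternative would make step 2 the identity). The reference column defaults to
the first reference channel of batch 1 and is configurable, because the
choice must be explicit for reproducibility. Zeros are floored at half the
smallest positive value before the log (configurable; `floor=None` turns
zeros into an error); negative values are always an error.

**Differential proteins.** Welch's unequal-variance *t* on log2 normalized
intensities, two-sided, with BH correction across *all* tested proteins
(matrisome subsetting is display-only; this is configurable since the
alternative — correcting within the matrisome subset — is also defensible).
Selection: |log2 FC| > 0.5 (fold-change > √2) and adjusted *p* < 0.01.
Positive fold-change means tumor-enriched. Category-level RPC differences use
the pooled-variance Student *t* (two-sided); protein level uses Welch — the
two tests are deliberately different because they are conventionally applied
at those two levels.

**Composition.** RPC is intensity ÷ per-sample total × 100; category RPC is
the sum of member-protein RPC. Top-*n* rankings break ties lexicographically
by protein id so output is deterministic. The 90 %-coverage count is the
greedy prefix on descending mean RPC. Over-representation of gene sets in a
DEP list uses the one-sided hypergeometric tail with BH across sets.

## Single-cell state discovery

**QC and preparation.** Cells with < 2000 total counts or < 500 detected
genes are treated as empty droplets and dropped (boundaries inclusive on the
keep side). Expression is library-size normalized to 10,000 counts per cell,
log1p-transformed, z-scored per gene, and negatives clamped to zero — NMF
requires non-negativity, and clamping keeps only above-average expression.
Genes that are numerically constant (sd ≤ 1e-10 relative) are set to zero
rather than amplified.

**NMF sweep.** Per tissue sample, one factorization per integer rank
K = 5…9 (sum = 35 modules per sample) using scikit-learn NMF with NNDSVD
initialization, which is deterministic for a fixed input; `max_iter` defaults
to 500 (300 in the fast pipeline/tests — the factorizations on the synthetic
matrices converge well before that). Samples with fewer cells than `k_max`
are skipped with a warning.

**Module filtering.** Modules are max-normalized (all-zero modules dropped),
restricted to the top-2000 genes by normalized dispersion (variance/mean,
z-scored within 20 equal-count mean bins), and kept when their summed weight
lies in [10, 150]. The bounds are the loose ends of the per-cell-type ranges
the procedure allows (10–20 lower, 150–170 upper) and are exposed as
configuration because no per-type mapping is published.

**Metaclustering.** Modules are embedded by their HVG weight vectors; a
k-nearest-neighbor graph (k = 15) on cosine similarity is built, edges are
weighted by the Jaccard overlap of neighbor sets *times* the cosine
similarity, and the graph is partitioned with Leiden (RBConfiguration,
resolution 1.0, fixed seed). The cosine factor keeps the graph informative
when the module count is small relative to k. Clustering happens on the
graph, not in a 2-D embedding: a stochastic embedding is not a reproducible
clustering substrate; UMAP-style coordinates are for display only. Each
cluster's program is the top 50 genes by mean normalized weight, ties broken
lexicographically.

**Quality filters and scoring.** A state is flagged when (i) > 25 % of its
program matches ribosomal/mitochondrial prefixes (RPS/RPL/MRPS/MRPL/MT-,
configurable), (ii) > 90 % of its member modules come from one study, or
(iii) a foreign major-type marker set is over-represented in the program
(hypergeometric *p* < 0.01). Cell scores are the mean program-gene expression
minus the mean of an expression-matched control set (25 expression bins,
50 controls per program gene, fixed seed) — the standard control-gene score.
A state whose mean score in any foreign major type exceeds its mean score in
its home type is dropped as soup/doublet contamination.

## Origin mapping

Markers: one-vs-rest Wilcoxon rank-sum (asymptotic, tie-corrected) per gene,
BH within each label, retained at adjusted *p* < 0.01 with positive effect
(log2 ratio of group means, ε = 1e-9). Origin: argmax of per-type mean
log-normalized expression, restricted to types where the gene is a
significant marker when any exist (otherwise unrestricted and flagged
non-specific); exact ties are flagged ambiguous and resolved
lexicographically. Protein↔gene reconciliation goes through an explicit
two-column mapping table — no implicit symbol munging, because silent
mismatches are the dominant failure mode of cross-omic joins. Fibroblast
substructure uses PCA on matrisome genes (20 components), the same SNN+Leiden
machinery at resolution 0.5, with the first two PCs as display coordinates.

## Deconvolution, signatures, survival

**Deconvolution** is non-negative least squares of each bulk sample against
the state-mean signature (genes intersected), fractions renormalized to sum
to 1. This is a transparent stand-in for reference-based tools: ν-SVR and
batch correction are deliberately not reproduced, which is why noiseless
recovery is exact but heavily noise-corrupted real bulk data would be harder.
The signature downsamples to ≤ 300 cells per state (uniform, seeded).

**ssGSEA**: genes ranked descending; in-set positions weighted by
rank^0.25 (the conventional exponent); score = Σ (weighted in-set ECDF −
uniform out-set ECDF). Scores are log2-transformed (shifted positive first
when a score ≤ 0 occurs, since the raw statistic can be negative) and
min-max normalized per gene set (z-score available). Group comparisons are
all-pairwise pooled *t*-tests with a compact letter display assigned by
insert-and-absorb.

**GSEA leading edge**: classic weighted Kolmogorov–Smirnov running sum on a
signal-to-noise ranking (sd floored at 0.2·|mean|); ES is the maximal
deviation; leading edge = in-set genes at/before the positive peak (or
at/after the negative trough).

**CMS4 molecules**: gene-level enrichment (GSEA leading edge over CMS4 vs
rest) intersected with protein-level enrichment (mean intensity in CMS4
strictly greater than the pooled non-CMS4 mean; a per-subtype variant is
available by flag since "greater than the other subtypes" admits both
readings). The two published fibroblast-associated molecule lists (13 PI16⁺
+ 7 desmoplastic) are shipped as constants; their unique union has 20
symbols.

**Survival**: PFS event = death or new tumor event (earliest day); otherwise
censored at last follow-up; nonpositive/missing times dropped with a logged
count. Stratification takes samples strictly above the 75th percentile vs
strictly below the 25th (midpoint quantile interpolation, which keeps both
groups non-empty for strongly bimodal scores); boundary ties are excluded
rather than assigned, since "top/bottom 25 %" does not define tie handling.
The comparison is the two-group log-rank chi-square (1 df, two-sided) with
Kaplan–Meier curves, via lifelines. The multi-gene score is the mean of
per-gene min-max-normalized expression; constant genes contribute 0 with a
warning. The 0.9 cutoff sometimes used to read such scores against subtype
probability is not given a fixed meaning here — the score definition is
explicit but no claim is made that it matches any particular figure axis.

## Synthetic-data generators

The generators produce the statistical structure each stage assumes, plus a
`SimTruth` record of every planted parameter:

- **TMT** (`gen_tmt_experiment`): per-protein baselines log-normal (log2
  mean 20, sd 2 — typical reporter-intensity magnitudes); multiplicative
  log-normal noise (log2 sd 0.3 by default) so log-ratios are Gaussian;
  a fraction (default 10 %) of proteins carries ±log2 FC (alternating sign)
  in the tumor group; reference columns are the pooled mean of all sample
  columns × {0.5, 1, 2} with the same noise model.
- **Single-cell** (`gen_sc_counts`): negative-binomial counts (dispersion
  0.5, log-normal cell size factors sd 0.2), 1500 cells × 800 genes,
  5 states with disjoint 60-gene programs overexpressed 6-fold, 10 exclusive
  markers per state, 4 studies with one tissue sample each. These sizes keep
  the full NMF sweep to seconds per sample while leaving the states
  separable; ≥ 95 % of cells pass the 2000-count/500-gene QC by
  construction.
- **Bulk** (`gen_bulk_mixtures`): fractions ~ Dirichlet(α = 1); additive
  Gaussian noise with sd = noise level × clean column mean, truncated at 0.
- **Survival** (`gen_survival`): exponential event times with hazard
  λ₀·exp(β·(score − mean)), λ₀ = ln 2 / 365 (median one year at the mean
  score); censoring by independent Bernoulli selection with the censor time
  uniform on (0, T).

What passing these tests shows — and does not. The generators plant clean,
disjoint programs, symmetric noise and exact mixing; real tissue has
correlated programs, batch effects, ambient RNA, isotope-impurity carryover
and peptide-level missingness, none of which are simulated (doublet/soup
structure only enters as explicitly constructed fixtures). Recovery at 100 %
sensitivity or ARI = 1.0 therefore validates the implementation logic, not
performance on real cohorts; the published headline counts (6,323 proteins,
407 matrisome proteins, 33 cell states, 68/21/20 molecules, 7 survival
genes) depend on the original deposited datasets and are out of scope.

## Numerical choices

- All randomness flows through explicit `numpy.random.Generator` seeds; no
  global state. Distinct logical draws use distinct derived seeds (seeding
  two generators with the same integer makes their streams identical, which
  silently correlates "independent" quantities).
- Ranking ties break lexicographically by identifier everywhere a ranking is
  emitted, making outputs byte-stable.
- Degenerate statistics are reported, not raised: zero-variance Pearson
  yields NaN; a constant-vs-constant *t* is p = 1 when means agree and p = 0
  when they differ (relevant for indicator-like fraction columns).
- BH adjustment uses statsmodels; Welch/Student *t*, hypergeometric,
  Mann-Whitney and Pearson use scipy; log-rank/KM use lifelines. Each is
  cross-checked in the test suite against an independent brute-force
  transcription (`tests/oracles.py`) to 1e-9 on small instances.

## Known limitations

- The NNLS deconvolution ignores platform/batch shift between signature and
  bulk; fractions on real cross-platform data will be biased accordingly.
- Module metaclustering quality depends on the weight-filter bounds; on data
  whose module weight distribution differs strongly from the synthetic
  regime the [10, 150] defaults may need adjustment.
- `find_markers` uses the asymptotic rank-sum approximation; for labels with
  very few cells an exact test would be preferable.
- The quartile log-rank chi-square is mildly anticonservative at small group
  sizes (the null rejection rate sits near 0.06 at 25 vs 25), a property of
  the asymptotic approximation rather than the implementation.
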