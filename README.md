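# stromamatrix

ECM-focused profiling of the tumor microenvironment, as a tested Python
library. The package implements the analysis chain used to characterise the
matrisome — the ensemble of extracellular-matrix (ECM) and ECM-associated
proteins — of colorectal tumors and their adjacent normal tissue (NAT), and
to connect differential ECM proteins to the fibroblast populations that
produce them:

1. **TMT matrisome proteomics** — pooled-reference-channel QC (references
   mixed 0.5 : 1 : 2, so per-protein log2 ratios concentrate at 1, 1, 2),
   two-step median-centering / reference-column normalization, relative
   percent composition (RPC = protein intensity ÷ summed intensity × 100),
   and differential proteins by Welch's *t* with Benjamini–Hochberg
   correction, selected at fold-change > √2 and adjusted *p* < 0.01.
2. **NMF cell-state discovery** — per-tissue non-negative matrix
   factorization at every rank K = 5…9 (35 gene-weight modules per sample),
   max-normalization, highly-variable-gene restriction, summed-weight
   filtering, and metaclustering of modules into consensus cell states with
   top-50 gene programs, followed by ribosomal/mitochondrial, single-study,
   foreign-marker and soup/doublet quality filters and per-cell scoring
   against expression-matched control gene sets.
3. **Cellular-origin mapping** — one-vs-rest Wilcoxon markers (BH within
   label, adjusted *p* < 0.01), origin = cell type with the highest average
   expression, and a cell-matrisome database linking each state to its
   matrisome markers.
4. **Subtype signatures and survival** — non-negative-least-squares bulk
   deconvolution against a 300-cell-downsampled state signature matrix,
   condition-enriched states (greatest median + all pairwise *t* *p* < 0.05),
   ssGSEA scoring with compact-letter displays, GSEA leading-edge extraction,
   gene × protein intersection defining the CMS4-enriched matrisome molecules
   (CMS4 = the mesenchymal, stroma-rich colorectal subtype), and top/bottom-
   quartile Kaplan–Meier log-rank stratification of progression-free
   survival.

Every stage has a seeded synthetic-data generator with planted ground truth
(`gen_tmt_experiment`, `gen_sc_counts`, `gen_bulk_mixtures`, `gen_survival`),
so the whole pipeline is testable end to end without any external download.

## Worked example

```python
import stromamatrix as sm

table, design, truth = sm.gen_tmt_experiment(
    n_proteins=1000, n_samples_per_group=8, frac_dep=0.1,
    log2fc=2.0, noise_sd=0.3, seed=7)

qc = sm.reference_ratio_qc(table, design)
print(qc.summary["median"].round(3))
# batch 1: 131N/131C 0.988, 131C/130N 0.978, 131N/130N 2.006
# -> the pooled-reference log2 ratios sit at the analytic values (1, 1, 2)
#    implied by the 0.5:1:2 mixing design.

dep = sm.dep_analysis(sm.normalize_intensities(table, design))
print(dep["selected"].sum(), (dep["direction"] == "Tumor-enriched").sum())
# 100 selected, 50 tumor-enriched: all 100 planted 4-fold changes are
# recovered at fold-change > sqrt(2), adjusted p < 0.01, with 0 false calls.
```

The `examples/` directory holds one short script per capability
(`tmt_proteomics.py`, `cell_state_discovery.py`, `origin_mapping.py`,
`bulk_deconvolution.py`, `cms4_signature_survival.py`); each builds a small
input, runs the method and prints what the numbers mean. A thin CLI wraps
the same functions:

```bash
stromamatrix demo --seed 0 --out runs/demo   # every stage + invariant checks
```

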