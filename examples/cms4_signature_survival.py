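"""Subtype matrisome signature definition and survival stratification.

Shows the gene/protein intersection that defines the CMS4-enriched matrisome
molecules (the two published fibroblast-associated lists union to 20
symbols), scores samples with ssGSEA, ranks genes for GSEA leading-edge
extraction, and stratifies simulated progression-free survival by the
top/bottom expression quartiles of a multi-gene score.
"""

import numpy as np
import pandas as pd

import stromamatrix as sm

molecules = sm.cms4_printed_molecules()
print(f"CMS4-enriched matrisome molecules: {len(molecules)}")
print(f"  PI16+ fibroblast-associated ({len(sm.PI16_FIBROBLAST_CMS4_MOLECULES)}): "
      f"{', '.join(sm.PI16_FIBROBLAST_CMS4_MOLECULES[:5])}, ...")
print(f"  desmoplastic-associated ({len(sm.DESMOPLASTIC_CMS4_MOLECULES)}): "
      f"{', '.join(sm.DESMOPLASTIC_CMS4_MOLECULES)}")

# simulated bulk cohort: molecule genes elevated in CMS4 samples
rng = np.random.default_rng(0)
genes = molecules + [f"BG{i:03d}" for i in range(180)]
subtypes = ["CMS4"] * 30 + ["CMS1"] * 25 + ["CMS2"] * 25 + ["CMS3"] * 20
expr = pd.DataFrame(rng.lognormal(2, 0.5, size=(len(genes), len(subtypes))),
                    index=genes, columns=[f"s{i}" for i in range(len(subtypes))])
expr.iloc[:20, :30] *= 2.5  # molecules up in CMS4

scores = sm.ssgsea_table(expr, {"cms4_matrisome": molecules})
_, letters = sm.pairwise_letter_display(
    scores.normalized["cms4_matrisome"], subtypes)
print(f"\nssGSEA compact letter display by subtype: {letters}")
print("(CMS4 carrying a letter no other subtype shares = significantly higher)")

stat = sm.signal_to_noise(expr, subtypes, "CMS4")
es, leading, _ = sm.gsea_leading_edge(stat, molecules)
print(f"\nGSEA enrichment score for the molecule set: {es:.3f}; "
      f"leading edge {len(leading)}/{len(molecules)} genes")

enriched_proteins = sm.cms4_protein_enrichment(expr, subtypes)
intersection = sm.intersect_signature(leading, enriched_proteins)
print(f"gene/protein intersection: {len(intersection)} molecules")

score = sm.multi_gene_score(expr, molecules[:7])
surv = sm.gen_survival(score, beta=2.0, censor_rate=0.2, seed=3)
res = sm.quartile_logrank(score, surv)
print(f"\nquartile log-rank on the 7-gene score: chi2={res.statistic:.1f}, "
      f"p={res.p_value:.2e} ({len(res.high_samples)} high vs "
      f"{len(res.low_samples)} low samples)")
# a small p confirms the planted hazard: high multi-gene score predicts
# earlier progression
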