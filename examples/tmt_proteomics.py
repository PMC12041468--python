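"""TMT matrisome proteomics on a simulated experiment.

Simulates a pooled-reference TMT experiment (references mixed 0.5:1:2),
checks the reference-channel log2 ratios against their analytic values
(1, 1, 2), normalizes, summarises matrisome composition (RPC) and calls
differential proteins at fold-change > sqrt(2), adjusted p < 0.01.
"""

import numpy as np

import stromamatrix as sm

table, design, truth = sm.gen_tmt_experiment(
    n_proteins=1000, n_samples_per_group=8, frac_dep=0.1,
    log2fc=2.0, noise_sd=0.3, seed=7,
)

qc = sm.reference_ratio_qc(table, design)
print("reference-channel log2 ratio medians (expect ~1, ~1, ~2):")
print(qc.summary["median"].round(3).to_string())

normalized = sm.normalize_intensities(table, design)
annotation = sm.matrisome_annotation_from_truth(truth)
rpc = sm.compute_rpc(normalized, annotation)
nat = table.samples_in_group("NAT")
print("\ntop 5 matrisome proteins by mean RPC in NAT (percent of total intensity):")
print(sm.top_composition(rpc, nat, n=5).round(3).to_string())
print(f"\nproteins covering 90% of NAT RPC: {sm.coverage_count(rpc, nat, 0.9)}")

dep = sm.dep_analysis(normalized)
found = set(dep.index[dep["selected"]])
planted = set(truth.dep_genes)
print(f"\nselected DEPs: {len(found)} "
      f"({(dep['direction'] == 'Tumor-enriched').sum()} tumor-enriched, "
      f"{(dep['direction'] == 'NAT-enriched').sum()} NAT-enriched)")
print(f"sensitivity vs planted truth: {len(found & planted) / len(planted):.0%}; "
      f"false discoveries: {len(found - planted)}")
# sensitivity ~100% and ~0 false discoveries show the Welch+BH selection
# recovers the planted 4-fold changes at this noise level
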