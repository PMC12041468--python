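"""Configured end-to-end demo pipeline on freshly generated synthetic data.

``run_pipeline`` executes every stage in dependency order — TMT simulation,
reference QC, normalization, composition, differential proteins; single-cell
simulation, state discovery, markers and origins; signature matrix, bulk
mixtures, deconvolution, enriched states; survival stratification — writing
plain-text outputs plus a machine-readable report of every invariant check.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellstates, origins, proteomics, signatures, simulate, survival
from . import io as smio


@dataclasses.dataclass
class PipelineConfig:
    """Per-stage parameters for the demo pipeline (all seeded)."""

    seed: int = 0
    version: str = "0.1.0"
    # TMT stage
    n_proteins: int = 600
    n_samples_per_group: int = 8
    n_batches: int = 2
    frac_dep: float = 0.1
    log2fc: float = 2.0
    tmt_noise_sd: float = 0.3
    dep_alpha: float = proteomics.DEP_ALPHA
    dep_log2fc_threshold: float = proteomics.DEP_LOG2FC_THRESHOLD
    # single-cell stage
    n_cells: int = 1200
    n_genes: int = 600
    n_states: int = 4
    program_size: int = 50
    n_markers_per_state: int = 10
    n_studies: int = 4
    k_min: int = 5
    k_max: int = 9
    nmf_max_iter: int = 300
    # bulk / survival stage
    n_bulk_samples: int = 80
    bulk_noise_sd: float = 0.05
    hazard_beta: float = 2.0
    censor_rate: float = 0.2

    def validate(self) -> None:
        if not 0 < self.dep_alpha < 1:
            raise ValueError("dep_alpha must lie in (0, 1)")
        if self.dep_log2fc_threshold < 0:
            raise ValueError("dep_log2fc_threshold must be >= 0")
        if not 0 <= self.frac_dep <= 1:
            raise ValueError("frac_dep must lie in [0, 1]")
        if self.tmt_noise_sd < 0 or self.bulk_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = cls(**(smio.read_yaml(path)))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        smio.write_yaml(dataclasses.asdict(self), path)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on synthetic data and check the invariant suite.

    Returns the report (also written to ``report.json``); ``all_passed``
    summarises the invariant checks.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checks: dict[str, bool] = {}
    outputs: list[str] = []

    def save(name: str):
        outputs.append(name)
        return out / name

    # --- proteomics stage --------------------------------------------------
    table, design, tmt_truth = simulate.gen_tmt_experiment(
        n_proteins=config.n_proteins,
        n_samples_per_group=config.n_samples_per_group,
        n_batches=config.n_batches,
        frac_dep=config.frac_dep,
        log2fc=config.log2fc,
        noise_sd=config.tmt_noise_sd,
        seed=config.seed,
    )
    smio.write_intensity_tsv(table, save("intensities.tsv"))
    smio.write_design_tsv(design, save("design.tsv"))
    tmt_truth.to_json(save("tmt_truth.json"))

    qc = proteomics.reference_ratio_qc(table, design)
    medians = qc.summary["median"]
    checks["reference_ratios_near_112"] = bool(
        all(
            abs(medians.loc[(b, name)] - expected) < 0.1
            for b in design.batches
            for name, expected in zip(proteomics.RATIO_NAMES, proteomics.EXPECTED_LOG2_RATIOS)
        )
    )
    qc.summary.reset_index().to_csv(save("reference_qc.tsv"), sep="\t", index=False)

    step1 = proteomics.median_center(table)
    log_medians = np.median(np.log2(step1), axis=0)
    checks["median_centered_columns_equal"] = bool(
        np.allclose(log_medians, log_medians[0], atol=1e-9)
    )
    normalized = proteomics.normalize_intensities(table, design)
    smio.write_tsv(normalized.data, save("normalized.tsv"))

    annotation = simulate.matrisome_annotation_from_truth(tmt_truth)
    rpc = proteomics.compute_rpc(normalized, annotation)
    checks["rpc_sums_to_100"] = bool(
        np.allclose(rpc.protein_pct.sum(axis=0), 100.0, atol=1e-6)
    )
    smio.write_tsv(rpc.protein_pct, save("rpc_proteins.tsv"))
    smio.write_tsv(rpc.category_pct, save("rpc_categories.tsv"))

    dep = proteomics.dep_analysis(
        normalized,
        log2fc_threshold=config.dep_log2fc_threshold,
        alpha=config.dep_alpha,
    )
    sel = dep[dep["selected"]]
    checks["dep_directions_disjoint"] = bool(
        (sel["direction"] != "ns").all()
        and sel.groupby("direction").size().sum() == len(sel)
    )
    planted = set(tmt_truth.dep_genes)
    if planted:
        found = set(sel.index)
        sens = len(planted & found) / len(planted)
        fdr = len(found - planted) / max(len(found), 1)
        checks["dep_sensitivity_ge_90"] = sens >= 0.90
        checks["dep_fdr_le_10"] = fdr <= 0.10
    smio.write_tsv(dep, save("dep.tsv"))

    # --- single-cell stage -------------------------------------------------
    adata, sc_truth = simulate.gen_sc_counts(
        n_cells=config.n_cells,
        n_genes=config.n_genes,
        n_states=config.n_states,
        program_size=config.program_size,
        n_markers_per_state=config.n_markers_per_state,
        n_studies=config.n_studies,
        seed=config.seed,
    )
    smio.write_counts_mtx(adata, out / "sc_counts")
    outputs += ["sc_counts.mtx", "sc_counts.barcodes.tsv", "sc_counts.features.tsv"]
    sc_truth.to_json(save("sc_truth.json"))

    disc = cellstates.discover_cell_states(
        adata,
        k_min=config.k_min,
        k_max=config.k_max,
        seed=config.seed,
        max_iter=config.nmf_max_iter,
    )
    expected_modules = sum(range(config.k_min, config.k_max + 1))
    checks["module_count_per_sample"] = all(
        v == expected_modules for v in disc.n_modules_per_sample.values()
    )
    smio.write_json(
        [
            {"state": s.state_id, "program": s.program, "flags": s.flags,
             "samples": s.samples}
            for s in disc.states
        ],
        save("cell_states.json"),
    )
    smio.write_tsv(disc.scores, save("state_scores.tsv"))

    good_states = [s for s in disc.states if s.passes_quality]
    usable = good_states or disc.states
    score_sub = disc.scores[[s.state_id for s in usable]]
    assigned = score_sub.idxmax(axis=1)
    truth_states = pd.Series(sc_truth.state_of_cell).loc[disc.adata.obs_names]
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(truth_states, assigned)
    checks["state_recovery_ari_ge_0.8"] = bool(ari >= 0.8)

    # --- origin mapping ----------------------------------------------------
    counts = np.asarray(disc.adata.X)
    lognorm = cellstates.log_normalize(counts)
    genes = disc.adata.var_names.tolist()
    labels = truth_states.to_numpy()
    markers = origins.find_markers(lognorm, labels, genes)
    planted_markers = [g for ms in sc_truth.marker_map.values() for g in ms]
    assignment = origins.assign_origin(planted_markers, lognorm, labels, genes, markers)
    correct = sum(
        assignment.table.loc[g, "origin"] == st
        for st, ms in sc_truth.marker_map.items()
        for g in ms
    )
    checks["origin_accuracy_ge_90"] = correct / len(planted_markers) >= 0.9
    smio.write_tsv(markers, save("markers.tsv"), index=False)
    smio.write_tsv(assignment.table, save("origins.tsv"))

    sc_annotation = _synthetic_sc_annotation(sc_truth)
    db = origins.build_cell_matrisome_db(markers, sc_annotation)
    smio.write_json({k: v for k, v in db.items()}, save("cell_matrisome_db.json"))

    # --- deconvolution + survival stage -------------------------------------
    signature = signatures.build_signature_matrix(lognorm, labels, genes, seed=config.seed)
    bulk, bulk_truth = simulate.gen_bulk_mixtures(
        signature,
        n_samples=config.n_bulk_samples,
        noise_sd=config.bulk_noise_sd,
        seed=config.seed,
    )
    fractions = signatures.deconvolve(bulk, signature)
    err = float(
        np.abs(fractions.values - bulk_truth.fractions.loc[fractions.index].values).mean()
    )
    checks["deconvolution_mean_abs_error_lt_0.02"] = err < 0.02
    smio.write_tsv(bulk, save("bulk_tpm.tsv"))
    smio.write_tsv(fractions, save("fractions.tsv"))

    dominant = bulk_truth.fractions.iloc[:, 0]
    condition = np.where(dominant > dominant.median(), "Tumor", "NAT")
    enriched = signatures.condition_enriched_state(fractions, condition)
    smio.write_json(enriched, save("enriched_states.json"))

    first_state = signature.index[0]
    top_genes = [g for g in sc_truth.program_map[first_state][:5]]
    score = signatures.multi_gene_score(bulk, top_genes)
    surv = simulate.gen_survival(
        score, beta=config.hazard_beta, censor_rate=config.censor_rate, seed=config.seed
    )
    result = survival.quartile_logrank(score, surv)
    checks["quartile_logrank_p_lt_0.05"] = result.p_value < 0.05
    smio.write_tsv(surv, save("survival.tsv"))
    smio.write_json(
        {"statistic": result.statistic, "p_value": result.p_value,
         "n_high": len(result.high_samples), "n_low": len(result.low_samples)},
        save("survival_summary.json"),
    )

    report = {
        "version": config.version,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": outputs,
        "metrics": {
            "state_recovery_ari": float(ari),
            "deconvolution_mean_abs_error": err,
            "logrank_p": result.p_value,
        },
        "checks": checks,
        "all_passed": all(checks.values()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _synthetic_sc_annotation(sc_truth) -> "proteomics.MatrisomeAnnotation":
    """Label every planted marker gene as a core matrisome gene so the demo
    cell-matrisome database has content (synthetic stand-in annotation)."""
    cats = ("COL", "GLY", "PRO")
    rows = {}
    for i, (state, ms) in enumerate(sorted(sc_truth.marker_map.items())):
        for g in ms:
            rows[g] = ("core", cats[i % len(cats)])
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["division", "category"])
    table.index.name = "gene"
    return proteomics.MatrisomeAnnotation(table)
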