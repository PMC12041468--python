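"""Synthetic data generators with planted ground truth.

Each generator emulates the statistical structure one pipeline stage assumes
and records every planted parameter in a :class:`SimTruth`, so downstream
recovery can be scored without any external download:

* TMT experiments: log-normal protein intensities, pooled reference channels
  mixed 0.5:1:2, planted signed log2 fold-changes on a fraction of proteins;
* single-cell counts: negative-binomial counts with planted per-state gene
  programs and exclusive marker genes;
* bulk mixtures: signature-weighted expression with known Dirichlet fractions;
* survival times: exponential with hazard proportional to exp(beta * score).

Every generator takes an explicit seed and draws from its own
``numpy.random.Generator``; no global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .proteomics import (
    ChannelDesign,
    IntensityTable,
    MatrisomeAnnotation,
    REFERENCE_CHANNELS,
    REFERENCE_WEIGHTS,
)

MATRISOME_CATEGORIES = ("COL", "GLY", "PRO", "REG", "AFF", "SEC")


@dataclass
class SimTruth:
    """Planted parameters of a synthetic dataset; the oracle for every
    recovery test downstream."""

    seed: int
    dep_genes: dict = field(default_factory=dict)  # gene -> signed log2 fold-change
    matrisome_flags: dict = field(default_factory=dict)  # gene -> category
    state_of_cell: dict = field(default_factory=dict)  # cell -> state id
    marker_map: dict = field(default_factory=dict)  # state -> exclusive marker genes
    program_map: dict = field(default_factory=dict)  # state -> program gene set
    fractions: pd.DataFrame | None = None  # bulk samples x states, rows sum to 1
    hazard_beta: float | None = None

    def validate(self) -> None:
        if self.fractions is not None:
            sums = self.fractions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("planted fractions must sum to 1 per sample")
        seen: set = set()
        for state, markers in self.marker_map.items():
            m = set(markers)
            if m & seen:
                raise ValueError("marker genes of distinct states must be disjoint")
            seen |= m

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "dep_genes": self.dep_genes,
            "matrisome_flags": self.matrisome_flags,
            "state_of_cell": self.state_of_cell,
            "marker_map": {k: list(v) for k, v in self.marker_map.items()},
            "program_map": {k: list(v) for k, v in self.program_map.items()},
            "fractions": None if self.fractions is None else self.fractions.to_dict(),
            "hazard_beta": self.hazard_beta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def gen_tmt_experiment(
    n_proteins: int = 1000,
    n_samples_per_group: int = 8,
    n_batches: int = 1,
    frac_dep: float = 0.1,
    log2fc: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    frac_matrisome: float = 0.4,
    base_log2_mean: float = 20.0,
    base_log2_sd: float = 2.0,
) -> tuple[IntensityTable, ChannelDesign, SimTruth]:
    """Simulate a TMT protein-intensity experiment with pooled references.

    Per-protein baseline abundances are log-normal (log2-scale mean
    ``base_log2_mean``, sd ``base_log2_sd``).  NAT and Tumor groups each get
    ``n_samples_per_group`` columns with multiplicative log-normal noise of
    log2-sd ``noise_sd``; a fraction ``frac_dep`` of proteins carries a
    planted fold-change of ``+log2fc`` or ``-log2fc`` (alternating sign) in
    the Tumor group.  Each batch adds three pooled-reference columns equal to
    the per-protein pooled mean scaled by 0.5 / 1 / 2 with the same noise
    model.  Matrisome category flags are planted on ``frac_matrisome`` of
    proteins, round-robin over the six categories.
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if n_samples_per_group < 1 or n_batches < 1:
        raise ValueError("counts must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= frac_dep <= 1:
        raise ValueError("frac_dep must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(1, n_proteins + 1)]
    base = base_log2_mean + base_log2_sd * rng.standard_normal(n_proteins)

    n_dep = int(round(frac_dep * n_proteins))
    dep_idx = rng.choice(n_proteins, size=n_dep, replace=False) if n_dep else np.array([], int)
    signs = np.where(np.arange(n_dep) % 2 == 0, 1.0, -1.0)
    delta = np.zeros(n_proteins)
    delta[dep_idx] = signs * log2fc

    groups, batches, columns = {}, {}, {}
    sample_names: dict[str, list[str]] = {"NAT": [], "Tumor": []}
    for group in ("NAT", "Tumor"):
        for i in range(n_samples_per_group):
            name = f"{group}_{i + 1:02d}"
            shift = delta if group == "Tumor" else 0.0
            log2v = base + shift + noise_sd * rng.standard_normal(n_proteins)
            columns[name] = np.exp2(log2v)
            groups[name] = group
            batches[name] = (i % n_batches) + 1
            sample_names[group].append(name)

    # pooled common control: equal-amount pool of every group sample
    pool = np.mean([columns[s] for s in sample_names["NAT"] + sample_names["Tumor"]], axis=0)
    design_rows = []
    for b in range(1, n_batches + 1):
        for channel, weight in zip(REFERENCE_CHANNELS, REFERENCE_WEIGHTS):
            name = f"B{b}_Ref_{channel}"
            noise = noise_sd * rng.standard_normal(n_proteins)
            columns[name] = pool * weight * np.exp2(noise)
            groups[name] = "Reference"
            batches[name] = b
            design_rows.append(
                {"batch": b, "channel": channel, "sample_id": name, "weight": weight}
            )

    data = pd.DataFrame(columns, index=pd.Index(proteins, name="protein"))
    design = ChannelDesign(
        table=pd.DataFrame(design_rows), reference_sample="B1_Ref_130N"
    )
    table = IntensityTable(
        data=data, groups=pd.Series(groups), batches=pd.Series(batches), scale="raw"
    )

    n_matrisome = int(round(frac_matrisome * n_proteins))
    mat_idx = rng.choice(n_proteins, size=n_matrisome, replace=False)
    flags = {
        proteins[i]: MATRISOME_CATEGORIES[j % len(MATRISOME_CATEGORIES)]
        for j, i in enumerate(sorted(mat_idx))
    }
    truth = SimTruth(
        seed=seed,
        dep_genes={proteins[i]: float(delta[i]) for i in dep_idx},
        matrisome_flags=flags,
    )
    truth.validate()
    return table, design, truth


def matrisome_annotation_from_truth(truth: SimTruth) -> MatrisomeAnnotation:
    """Turn planted category flags into a MatrisomeAnnotation table."""
    core = {"COL", "GLY", "PRO"}
    rows = {
        gene: ("core" if cat in core else "associated", cat)
        for gene, cat in truth.matrisome_flags.items()
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["division", "category"])
    table.index.name = "gene"
    return MatrisomeAnnotation(table)


def gen_sc_counts(
    n_cells: int = 1500,
    n_genes: int = 800,
    n_states: int = 5,
    program_size: int = 60,
    n_markers_per_state: int = 10,
    n_studies: int = 4,
    seed: int = 0,
    samples_per_study: int = 1,
    baseline_mean: float = 4.0,
    program_fold: float = 6.0,
    dispersion: float = 0.5,
    cell_size_sd: float = 0.2,
) -> tuple[ad.AnnData, SimTruth]:
    """Simulate a single-cell count matrix with planted cell states.

    Counts are negative binomial (mean ``mu``, variance ``mu + dispersion *
    mu^2``) with a log-normal per-cell size factor.  Cells are assigned to
    ``n_states`` states round-robin; each state overexpresses its disjoint
    ``program_size``-gene program by ``program_fold``; the first
    ``n_markers_per_state`` program genes are the state's exclusive markers
    (baseline expression everywhere else).  Study labels are assigned
    round-robin over cells; each study contributes ``samples_per_study``
    tissue samples alternating NAT/Tumor condition.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_states * program_size > n_genes:
        raise ValueError("programs would overlap: n_states * program_size > n_genes")
    if n_markers_per_state > program_size:
        raise ValueError("n_markers_per_state cannot exceed program_size")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(1, n_genes + 1)]
    cells = [f"C{i:05d}" for i in range(1, n_cells + 1)]
    states = [f"state_{chr(ord('A') + s)}" for s in range(n_states)]

    program_map = {
        states[s]: genes[s * program_size : (s + 1) * program_size] for s in range(n_states)
    }
    marker_map = {s: program_map[s][:n_markers_per_state] for s in states}
    state_idx = np.arange(n_cells) % n_states
    study_idx = np.arange(n_cells) % n_studies
    sample_idx = study_idx * samples_per_study + (np.arange(n_cells) // n_studies) % samples_per_study

    mu = np.full((n_cells, n_genes), baseline_mean)
    for s in range(n_states):
        rows = state_idx == s
        mu[np.ix_(rows, np.arange(s * program_size, (s + 1) * program_size))] *= program_fold
    size_factor = np.exp(cell_size_sd * rng.standard_normal(n_cells))
    mu *= size_factor[:, None]

    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    obs = pd.DataFrame(
        {
            "sample": [f"S{int(i) + 1:02d}" for i in sample_idx],
            "study": [f"study_{int(i) + 1}" for i in study_idx],
            "condition": ["Tumor" if int(i) % 2 else "NAT" for i in sample_idx],
        },
        index=pd.Index(cells, name="cell"),
    )
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = SimTruth(
        seed=seed,
        state_of_cell={cells[i]: states[state_idx[i]] for i in range(n_cells)},
        marker_map=marker_map,
        program_map=program_map,
    )
    truth.validate()
    return adata, truth


def gen_bulk_mixtures(
    signature: pd.DataFrame,
    n_samples: int = 50,
    dirichlet_alpha: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Mix state expression profiles into bulk samples with known fractions.

    ``signature`` is states x genes (non-negative).  Each bulk column equals
    ``signature.T @ f`` with ``f ~ Dirichlet(alpha)``, plus additive Gaussian
    noise with sd ``noise_sd`` times the clean column mean, truncated at 0.
    """
    if signature.size == 0:
        raise ValueError("empty signature")
    if (signature.values < 0).any():
        raise ValueError("signature must be non-negative")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    states, genes = signature.index, signature.columns
    fracs = rng.dirichlet(np.full(len(states), dirichlet_alpha), size=n_samples)
    clean = fracs @ signature.values  # samples x genes
    if noise_sd > 0:
        scale = noise_sd * clean.mean(axis=1, keepdims=True)
        clean = np.maximum(clean + scale * rng.standard_normal(clean.shape), 0.0)
    samples = [f"Bulk_{i + 1:03d}" for i in range(n_samples)]
    bulk = pd.DataFrame(clean.T, index=genes, columns=samples)
    truth = SimTruth(
        seed=seed, fractions=pd.DataFrame(fracs, index=samples, columns=states)
    )
    truth.validate()
    return bulk, truth


def gen_survival(
    score: pd.Series,
    beta: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = np.log(2) / 365.0,
) -> pd.DataFrame:
    """Simulate survival times with hazard proportional to exp(beta * score).

    Event times are exponential with rate ``baseline_hazard * exp(beta *
    (score - mean(score)))``.  Each subject is independently censored with
    probability ``censor_rate``; a censored subject's time is uniform on
    (0, T).  Returns a frame with columns time (> 0) and event (0/1).
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    s = score.to_numpy(float)
    rate = baseline_hazard * np.exp(beta * (s - s.mean()))
    times = rng.exponential(1.0 / rate)
    censored = rng.random(len(s)) < censor_rate
    obs_times = np.where(censored, rng.uniform(0, times), times)
    obs_times = np.maximum(obs_times, 1e-9)
    return pd.DataFrame(
        {"time": obs_times, "event": (~censored).astype(int)}, index=score.index
    )
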