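"""Consensus cell-state discovery from single-cell counts via per-sample NMF.

The procedure factorizes each tissue sample's prepared expression matrix with
non-negative matrix factorization at every integer rank K in a sweep (default
5..9, i.e. 35 modules per sample), max-normalizes the resulting gene-weight
modules, restricts them to highly variable genes, filters on summed weight,
and metaclusters the surviving modules across samples on a shared-nearest-
neighbor cosine graph.  Each module cluster defines a cell state whose
program is the top 50 genes by mean normalized weight.  States are then
quality-filtered (ribosomal/mitochondrial domination, single-study origin,
foreign-marker contamination) and scored per cell against expression-matched
control gene sets; states scoring higher in a foreign major type than in
their home type are dropped as soup/doublet artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF

import anndata as ad

QC_MIN_COUNTS = 2000
QC_MIN_GENES = 500
RIBO_MITO_PREFIXES = ("RPS", "RPL", "MRPS", "MRPL", "MT-")


@dataclass
class NMFModule:
    """One gene-weight factor from a single sample's NMF at one rank."""

    sample: str
    k: int
    index: int
    weights: np.ndarray  # over the full gene list used for factorization
    max_normalized: bool = False
    hvg_weights: np.ndarray | None = None
    summed_weight: float | None = None

    @property
    def name(self) -> str:
        return f"{self.sample}|K{self.k}|{self.index}"


@dataclass
class CellState:
    """A consensus NMF metamodule: a top-50 gene program plus provenance."""

    state_id: str
    program: list  # ordered, <= 50 unique genes
    member_modules: list  # NMFModule references
    flags: dict = field(default_factory=dict)

    @property
    def samples(self) -> list:
        return sorted({m.sample for m in self.member_modules})

    @property
    def passes_quality(self) -> bool:
        return not any(self.flags.values())


def qc_filter(
    adata: ad.AnnData,
    min_counts: int = QC_MIN_COUNTS,
    min_genes: int = QC_MIN_GENES,
) -> ad.AnnData:
    """Drop empty-droplet-like cells: keep cells with total counts >=
    ``min_counts`` AND detected genes >= ``min_genes`` (boundaries inclusive);
    counts are untouched."""
    X = np.asarray(adata.X)
    totals = X.sum(axis=1)
    detected = (X > 0).sum(axis=1)
    keep = (totals >= min_counts) & (detected >= min_genes)
    if not keep.any():
        raise ValueError("QC removed every cell; check thresholds/input")
    return adata[keep].copy()


def log_normalize(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Library-size normalize each cell to ``target_sum`` and log1p."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * target_sum)


def center_clamp(lognorm: np.ndarray) -> np.ndarray:
    """Z-score each gene across cells and clamp negatives to zero, yielding
    the non-negative matrix NMF requires.  Constant genes become all-zero."""
    mu = lognorm.mean(axis=0, keepdims=True)
    sd = lognorm.std(axis=0, ddof=0, keepdims=True)
    constant = sd <= 1e-10 * (np.abs(mu) + 1.0)  # numerically constant genes
    z = (lognorm - mu) / np.where(constant, 1.0, sd)
    z = np.where(constant, 0.0, z)
    return np.maximum(z, 0.0)


def prepare_expression(counts: np.ndarray, target_sum: float = 1e4) -> np.ndarray:
    """Full preparation for NMF: log-normalize, z-center per gene, clamp
    negatives to zero (output is element-wise >= 0)."""
    return center_clamp(log_normalize(counts, target_sum))


def per_sample_nmf(
    expr: np.ndarray,
    samples: pd.Series | np.ndarray,
    k_min: int = 5,
    k_max: int = 9,
    seed: int = 0,
    max_iter: int = 500,
) -> list[NMFModule]:
    """Factorize each sample's cells at every rank K in [k_min, k_max].

    Every gene factor is kept as a module, so each sample yields
    sum(k_min..k_max) modules (35 for the default 5..9 sweep).  NNDSVD
    initialization makes the factorization deterministic for a fixed seed.
    Samples with fewer than ``k_max`` cells are skipped with a warning.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    expr = np.asarray(expr, dtype=float)
    if (expr < 0).any():
        raise ValueError("expression must be non-negative (run prepare_expression)")
    samples = np.asarray(samples)
    modules: list[NMFModule] = []
    for sample in pd.unique(samples):
        rows = samples == sample
        sub = expr[rows]
        if sub.shape[0] < k_max:
            warnings.warn(f"sample {sample}: fewer than {k_max} cells, skipped")
            continue
        for k in range(k_min, k_max + 1):
            model = NMF(
                n_components=k,
                init="nndsvd",
                random_state=seed,
                max_iter=max_iter,
                tol=1e-4,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # convergence warnings at small max_iter
                model.fit(sub)
            for i, row in enumerate(model.components_):
                modules.append(NMFModule(sample=str(sample), k=k, index=i, weights=row.copy()))
    return modules


def highly_variable_genes(expr: np.ndarray, n_top: int = 2000, n_bins: int = 20) -> np.ndarray:
    """Indices of the ``n_top`` genes by normalized dispersion.

    Dispersion = variance / mean per gene; dispersions are z-scored within
    equal-count mean bins before ranking, so highly expressed genes do not
    dominate.
    """
    expr = np.asarray(expr, dtype=float)
    mean = expr.mean(axis=0)
    var = expr.var(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean, kind="stable")
    n_genes = len(mean)
    norm_disp = np.zeros(n_genes)
    bins = np.array_split(order, min(n_bins, n_genes))
    for b in bins:
        d = disp[b]
        sd = d.std(ddof=0)
        norm_disp[b] = (d - d.mean()) / sd if sd > 0 else 0.0
    top = np.argsort(-norm_disp, kind="stable")[: min(n_top, n_genes)]
    return np.sort(top)


def filter_modules(
    modules: list[NMFModule],
    expr: np.ndarray,
    hvg_count: int = 2000,
    min_weight: float = 10.0,
    max_weight: float = 150.0,
) -> tuple[list[NMFModule], np.ndarray]:
    """Max-normalize modules, restrict to highly variable genes, and keep
    modules whose summed HVG weight lies in [min_weight, max_weight].

    Returns the retained modules (with ``hvg_weights`` and ``summed_weight``
    populated) and the HVG index used.  All-zero modules are dropped.
    """
    hvg = highly_variable_genes(expr, n_top=hvg_count)
    kept: list[NMFModule] = []
    for mod in modules:
        mx = mod.weights.max()
        if mx <= 0:
            continue
        norm = mod.weights / mx
        hw = norm[hvg]
        s = float(hw.sum())
        if min_weight <= s <= max_weight:
            mod.weights = norm
            mod.max_normalized = True
            mod.hvg_weights = hw
            mod.summed_weight = s
            kept.append(mod)
    if modules and not kept:
        raise ValueError(
            "every module was filtered out; relax min_weight/max_weight bounds"
        )
    return kept, hvg


def _snn_graph(vectors: np.ndarray, n_neighbors: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph on cosine distances, Jaccard-weighted."""
    m = vectors.shape[0]
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = vectors / norms
    sim = unit @ unit.T
    k = min(n_neighbors, m - 1)
    neighbor_sets = []
    for i in range(m):
        order = np.argsort(-sim[i], kind="stable")
        order = order[order != i][:k]
        neighbor_sets.append(set(order.tolist()) | {i})
    edges, weights = [], []
    for i in range(m):
        for j in range(i + 1, m):
            if j in neighbor_sets[i] or i in neighbor_sets[j]:
                inter = len(neighbor_sets[i] & neighbor_sets[j])
                union = len(neighbor_sets[i] | neighbor_sets[j])
                # scale neighbor-set overlap by cosine similarity so the
                # graph stays informative when k approaches the module count
                w = (inter / union) * max(float(sim[i, j]), 0.0)
                if w > 0:
                    edges.append((i, j))
                    weights.append(w)
    g = igraph.Graph(n=m, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_modules_to_states(
    modules: list[NMFModule],
    resolution: float = 1.0,
    n_neighbors: int = 15,
    top_n: int = 50,
    seed: int = 0,
    genes: list | None = None,
    hvg_index: np.ndarray | None = None,
) -> list[CellState]:
    """Metacluster filtered modules into consensus cell states.

    Modules are embedded by their max-normalized HVG weight vectors; a
    shared-nearest-neighbor graph on cosine similarity is partitioned with
    the Leiden algorithm at ``resolution``.  Per cluster, genes are ranked by
    mean normalized weight (ties broken lexicographically) and the top
    ``top_n`` form the state program.  ``genes`` gives symbols for the full
    gene axis; ``hvg_index`` maps ``hvg_weights`` back onto it.
    """
    if not modules:
        raise ValueError("no modules to cluster")
    vecs = np.vstack([m.hvg_weights if m.hvg_weights is not None else m.weights for m in modules])
    if len(modules) == 1:
        labels = np.array([0])
    else:
        g = _snn_graph(vecs, n_neighbors)
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=g.es["weight"] if g.ecount() else None,
            resolution_parameter=resolution,
            seed=seed,
        )
        labels = np.asarray(part.membership)

    if genes is not None:
        gene_names = np.asarray(genes)
        if hvg_index is not None and vecs.shape[1] == len(hvg_index):
            gene_names = gene_names[hvg_index]
    else:
        gene_names = np.array([f"g{i}" for i in range(vecs.shape[1])])

    states: list[CellState] = []
    for lab in sorted(set(labels.tolist())):
        members = [modules[i] for i in np.flatnonzero(labels == lab)]
        mean_w = vecs[labels == lab].mean(axis=0)
        order = sorted(range(len(mean_w)), key=lambda j: (-mean_w[j], str(gene_names[j])))
        top = [str(gene_names[j]) for j in order[: min(top_n, len(order))] if mean_w[j] > 0]
        states.append(
            CellState(state_id=f"NMF_state_{lab}", program=top, member_modules=members)
        )
    return states


def quality_filter_states(
    states: list[CellState],
    study_of_sample: dict,
    ribo_mito_frac: float = 0.25,
    study_frac: float = 0.9,
    foreign_marker_sets: dict | None = None,
    universe_genes: list | None = None,
    ribo_mito_prefixes: tuple = RIBO_MITO_PREFIXES,
    marker_alpha: float = 0.01,
) -> list[CellState]:
    """Flag low-quality states in place and return the list.

    Flags: ``ribo_mito`` when more than ``ribo_mito_frac`` of program genes
    carry a ribosomal/mitochondrial prefix; ``single_study`` when more than
    ``study_frac`` of member modules come from one study; ``foreign_markers``
    when any foreign major-type marker set is over-represented in the program
    (hypergeometric p < ``marker_alpha``).
    """
    for state in states:
        program = state.program
        n_rm = sum(
            any(str(g).upper().startswith(p) for p in ribo_mito_prefixes) for g in program
        )
        state.flags["ribo_mito"] = bool(program) and n_rm / len(program) > ribo_mito_frac

        studies = [study_of_sample.get(m.sample, m.sample) for m in state.member_modules]
        if studies:
            top_share = max(studies.count(s) for s in set(studies)) / len(studies)
            state.flags["single_study"] = top_share > study_frac
        if foreign_marker_sets and universe_genes is not None:
            universe = set(map(str, universe_genes))
            prog = set(map(str, program)) & universe
            flagged = False
            for _type, markers in foreign_marker_sets.items():
                mk = set(map(str, markers)) & universe
                k = len(prog & mk)
                p = float(stats.hypergeom.sf(k - 1, len(universe), len(mk), len(prog)))
                if p < marker_alpha:
                    flagged = True
                    break
            state.flags["foreign_markers"] = flagged
    return states


def score_cells(
    states: list[CellState],
    expr: np.ndarray,
    genes: list,
    n_bins: int = 25,
    ctrl_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every cell for every state program.

    Score = mean expression of the program genes minus the mean of a control
    gene set matched on average expression (genes binned into ``n_bins``
    equal-count bins; ``ctrl_size`` controls sampled per program gene, fixed
    seed).  Program genes absent from the matrix are dropped with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    gene_index = {str(g): i for i, g in enumerate(genes)}
    avg = expr.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of_gene = np.zeros(len(genes), dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, len(genes)))):
        bin_of_gene[chunk] = b
    bin_members = {b: np.flatnonzero(bin_of_gene == b) for b in np.unique(bin_of_gene)}
    rng = np.random.default_rng(seed)

    scores = {}
    for state in states:
        idx = [gene_index[g] for g in state.program if g in gene_index]
        if len(idx) < len(state.program):
            warnings.warn(
                f"{state.state_id}: {len(state.program) - len(idx)} program genes absent; "
                "scoring on the intersection"
            )
        if not idx:
            scores[state.state_id] = np.zeros(expr.shape[0])
            continue
        ctrl: set = set()
        for gi in idx:
            pool = bin_members[bin_of_gene[gi]]
            take = min(ctrl_size, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
        ctrl -= set(idx)
        ctrl_idx = np.fromiter(ctrl, dtype=int) if ctrl else np.array(idx)
        scores[state.state_id] = expr[:, idx].mean(axis=1) - expr[:, ctrl_idx].mean(axis=1)
    return pd.DataFrame(scores)


def drop_contaminated(
    scores: pd.DataFrame,
    major_type: pd.Series | np.ndarray,
    home_type: dict,
) -> tuple[list[str], list[str]]:
    """Soup/doublet removal: a state whose mean score in any foreign major
    type exceeds its mean score in its home type is dropped.

    ``home_type`` maps state id -> the major type whose cells the state was
    derived from.  Returns (kept state ids, dropped state ids).
    """
    major_type = np.asarray(major_type)
    kept, dropped = [], []
    for state in scores.columns:
        home = home_type.get(state)
        if home is None or home not in major_type:
            kept.append(state)
            continue
        col = scores[state].to_numpy()
        home_mean = col[major_type == home].mean()
        foreign = [
            col[major_type == t].mean() for t in pd.unique(major_type) if t != home
        ]
        if foreign and max(foreign) > home_mean:
            dropped.append(state)
        else:
            kept.append(state)
    return kept, dropped


@dataclass
class StateDiscoveryResult:
    states: list
    scores: pd.DataFrame  # cells x states
    adata: ad.AnnData  # QC-filtered input
    modules: list  # all modules from the NMF sweep, before filtering
    filtered_modules: list
    n_modules_per_sample: dict


def discover_cell_states(
    adata: ad.AnnData,
    sample_key: str = "sample",
    study_key: str = "study",
    k_min: int = 5,
    k_max: int = 9,
    hvg_count: int = 2000,
    min_weight: float = 10.0,
    max_weight: float = 150.0,
    resolution: float = 1.0,
    seed: int = 0,
    max_iter: int = 500,
) -> StateDiscoveryResult:
    """End-to-end state discovery on raw counts.

    QC-filters cells, prepares expression, runs the per-sample NMF sweep,
    filters and metaclusters modules, quality-flags states and scores every
    cell.
    """
    adata = qc_filter(adata)
    counts = np.asarray(adata.X)
    lognorm = log_normalize(counts)
    expr = center_clamp(lognorm)
    modules = per_sample_nmf(
        expr, adata.obs[sample_key], k_min=k_min, k_max=k_max, seed=seed, max_iter=max_iter
    )
    kept, hvg = filter_modules(
        modules, expr, hvg_count=hvg_count, min_weight=min_weight, max_weight=max_weight
    )
    genes = adata.var_names.tolist()
    states = cluster_modules_to_states(
        kept, resolution=resolution, seed=seed, genes=genes, hvg_index=hvg
    )
    study_of_sample = (
        adata.obs.drop_duplicates(sample_key).set_index(sample_key)[study_key].to_dict()
        if study_key in adata.obs
        else {}
    )
    quality_filter_states(states, study_of_sample)
    scores = score_cells(states, lognorm, genes, seed=seed)
    scores.index = adata.obs_names
    counts_per_sample = pd.Series([m.sample for m in modules]).value_counts().to_dict()
    return StateDiscoveryResult(
        states=states,
        scores=scores,
        adata=adata,
        modules=modules,
        filtered_modules=kept,
        n_modules_per_sample=counts_per_sample,
    )
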