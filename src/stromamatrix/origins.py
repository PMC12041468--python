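"""Cellular-origin mapping of ECM proteins and the cell-matrisome database.

Cell-type-specific genes are detected with a one-vs-rest Wilcoxon rank-sum
test (BH-corrected within each label, adjusted p < 0.01, positive effect).
A gene's cellular origin is the cell type/state with the highest average
log-normalized expression, restricted to types where the gene is a
significant marker whenever any exist.  Matrisome-annotated markers of each
state form the cell-matrisome database, which links differential ECM
proteins back to the fibroblast states that produce them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .cellstates import _snn_graph
from .proteomics import MatrisomeAnnotation

import leidenalg

MARKER_ALPHA = 0.01


def find_markers(
    expr: np.ndarray,
    labels,
    genes,
    alpha: float = MARKER_ALPHA,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker detection.

    For each label, every gene is tested in the label's cells against all
    other cells (two-sided asymptotic Mann-Whitney with tie correction);
    p-values are BH-corrected across genes within the label.  Retained
    markers have adjusted p < ``alpha`` and positive effect (log2 ratio of
    group means).  Labels with fewer than ``min_cells`` cells are excluded
    with a warning.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    genes = np.asarray(genes)
    if len(pd.unique(labels)) < 2:
        raise ValueError("need at least two labels")
    rows = []
    eps = 1e-9
    for label in pd.unique(labels):
        mask = labels == label
        if mask.sum() < min_cells:
            warnings.warn(f"label {label!r} has < {min_cells} cells; excluded")
            continue
        x = expr[mask]
        y = expr[~mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided", method="asymptotic")
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        q = multipletests(p, method="fdr_bh")[1]
        effect = np.log2((x.mean(axis=0) + eps) / (y.mean(axis=0) + eps))
        keep = (q < alpha) & (effect > 0)
        for j in np.flatnonzero(keep):
            rows.append(
                {
                    "gene": str(genes[j]),
                    "label": str(label),
                    "p": float(p[j]),
                    "q": float(q[j]),
                    "effect": float(effect[j]),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "label", "p", "q", "effect"])


@dataclass
class OriginAssignment:
    """Per-gene cellular origin with the per-type mean expression backing it."""

    table: pd.DataFrame  # index gene: origin, ambiguous, nonspecific, unassigned
    means: pd.DataFrame  # types x genes mean expression


def assign_origin(
    query_genes,
    expr: np.ndarray,
    labels,
    genes,
    markers: pd.DataFrame | None = None,
) -> OriginAssignment:
    """Assign each gene's origin to the type with the highest mean expression.

    ``expr`` is cells x genes (log-normalized) with gene axis ``genes``.
    When the gene is a significant marker of one or more types, the argmax is
    restricted to those types; otherwise the unrestricted argmax is used and
    the gene is flagged non-specific.  Exact ties are flagged ambiguous and
    the lexicographically smallest type reported.  Genes absent from the
    matrix are recorded as unassigned.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    by_name = {str(t): t for t in pd.unique(labels)}
    means = pd.DataFrame(
        {name: expr[labels == raw].mean(axis=0) for name, raw in sorted(by_name.items())},
        index=pd.Index([str(g) for g in genes]),
    ).T
    return _assign_from_means(query_genes, means, markers)


def _assign_from_means(
    query_genes, means: pd.DataFrame, markers: pd.DataFrame | None
) -> OriginAssignment:
    marker_types: dict[str, set] = {}
    if markers is not None and len(markers):
        for gene, sub in markers.groupby("gene"):
            marker_types[str(gene)] = set(map(str, sub["label"]))
    rows = []
    for gene in query_genes:
        g = str(gene)
        if g not in means.columns:
            rows.append({"gene": g, "origin": None, "ambiguous": False,
                         "nonspecific": False, "unassigned": True})
            continue
        col = means[g]
        restrict = sorted(marker_types.get(g, set()) & set(col.index))
        nonspecific = not restrict
        cand = col.loc[restrict] if restrict else col
        top = cand.max()
        winners = sorted(cand.index[cand == top])
        rows.append(
            {
                "gene": g,
                "origin": winners[0],
                "ambiguous": len(winners) > 1,
                "nonspecific": nonspecific,
                "unassigned": False,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    return OriginAssignment(table=table, means=means)


def map_dep_origins(
    dep: pd.DataFrame,
    assignment: OriginAssignment,
    symbol_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join selected differential proteins to their cellular origins.

    ``symbol_map`` (optional) is a two-column frame mapping protein ids to
    gene symbols; without it protein ids are used as symbols directly.
    Returns one row per selected protein: direction, gene, origin (or
    'unannotated') and flags, suitable for per-direction/per-type counting
    with ``summarize_dep_origins``.
    """
    if "selected" not in dep.columns:
        raise ValueError("expected a DEP table with a 'selected' column")
    mapping = {}
    if symbol_map is not None:
        a, b = symbol_map.columns[:2]
        mapping = dict(zip(symbol_map[a].astype(str), symbol_map[b].astype(str)))
    rows = []
    for protein, row in dep[dep["selected"]].iterrows():
        gene = mapping.get(str(protein), str(protein))
        if gene in assignment.table.index and not assignment.table.loc[gene, "unassigned"]:
            origin = assignment.table.loc[gene, "origin"]
            nonspecific = bool(assignment.table.loc[gene, "nonspecific"])
        else:
            origin, nonspecific = "unannotated", False
        rows.append(
            {
                "protein": str(protein),
                "gene": gene,
                "direction": row["direction"],
                "origin": origin,
                "nonspecific": nonspecific,
            }
        )
    return pd.DataFrame(rows, columns=["protein", "gene", "direction", "origin", "nonspecific"])


def summarize_dep_origins(mapped: pd.DataFrame) -> pd.DataFrame:
    """Counts of selected differential proteins per direction per origin."""
    if mapped.empty:
        return pd.DataFrame()
    return mapped.pivot_table(
        index="direction", columns="origin", values="protein", aggfunc="count", fill_value=0
    )


def build_cell_matrisome_db(
    markers: pd.DataFrame, annotation: MatrisomeAnnotation
) -> dict[str, list[tuple[str, str]]]:
    """Cell-matrisome database: per state/type, its matrisome-annotated
    significant markers as (gene, category) pairs ordered by effect size
    (descending, ties lexicographic)."""
    db: dict[str, list[tuple[str, str]]] = {}
    if markers.empty:
        return db
    for label, sub in markers.groupby("label"):
        entries = [
            (str(r["gene"]), annotation.lookup(r["gene"])[1], float(r["effect"]))
            for _, r in sub.iterrows()
            if annotation.is_matrisome(r["gene"])
        ]
        entries.sort(key=lambda t: (-t[2], t[0]))
        db[str(label)] = [(g, c) for g, c, _ in entries]
    return db


def fibroblast_matrisome_embedding(
    expr: np.ndarray,
    genes,
    annotation: MatrisomeAnnotation,
    n_pcs: int = 20,
    resolution: float = 0.5,
    n_neighbors: int = 15,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster fibroblasts on their matrisome-gene expression.

    PCA on the matrisome-gene submatrix (z-scaled per gene), a shared-
    nearest-neighbor graph on the leading ``n_pcs`` components, and Leiden
    community detection at ``resolution``.  Returns (cluster labels, 2-D
    coordinates = first two principal components, used for display).
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[0] == 0:
        raise ValueError("empty fibroblast subset")
    genes = np.asarray([str(g) for g in genes])
    mat_mask = np.array([annotation.is_matrisome(g) for g in genes])
    if mat_mask.sum() < n_pcs:
        warnings.warn(
            f"only {int(mat_mask.sum())} matrisome genes present; using all of them"
        )
    sub = expr[:, mat_mask] if mat_mask.any() else expr
    mu = sub.mean(axis=0, keepdims=True)
    sd = sub.std(axis=0, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    n_comp = min(n_pcs, z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=max(n_comp, 1), svd_solver="full")
    comps = pca.fit_transform(z)
    g = _snn_graph(comps, n_neighbors=min(n_neighbors, comps.shape[0] - 1))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"] if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership)
    coords = comps[:, : min(2, comps.shape[1])]
    return labels, coords
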