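"""Subtype-specific matrisome signatures: bulk deconvolution into cell-state
fractions, condition-enriched states, gene-set scoring (ssGSEA / GSEA leading
edge), CMS4-enriched molecule intersection, and multi-gene scores.

Deconvolution estimates per-sample non-negative cell-state fractions by
least squares against a single-cell signature matrix (mean expression over at
most 300 downsampled cells per state) and renormalizes the fractions to sum
to one.  This is a transparent NNLS stand-in for reference-based
deconvolution tools; support-vector regression and batch correction are
deliberately not reproduced.

The consensus molecular subtypes of colorectal cancer (CMS1-4) enter as
per-sample labels/probabilities; CMS4 is the mesenchymal, stroma-rich
subtype whose matrisome signature this module assembles by intersecting
gene-level (GSEA leading edge) and protein-level (mean-intensity) enrichment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

#: CMS4-enriched matrisome molecules printed in the study's results,
#: grouped by the fibroblast state they are associated with.
PI16_FIBROBLAST_CMS4_MOLECULES = (
    "DPT", "MGP", "SFRP2", "PRELP", "OGN", "SRPX", "COL14A1",
    "FBLN2", "LUM", "ABI3BP", "FBLN1", "DCN", "CCN5",
)
DESMOPLASTIC_CMS4_MOLECULES = (
    "THBS2", "CTHRC1", "BGN", "TIMP2", "VCAN", "MMP2", "TNC",
)


def cms4_printed_molecules() -> list[str]:
    """Unique union of the two published CMS4 molecule lists (order kept)."""
    seen, out = set(), []
    for g in PI16_FIBROBLAST_CMS4_MOLECULES + DESMOPLASTIC_CMS4_MOLECULES:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def build_signature_matrix(
    expr: np.ndarray,
    labels,
    genes,
    cap: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """States x genes mean expression over at most ``cap`` cells per state.

    Cells are downsampled uniformly without replacement (all cells when a
    state has fewer than ``cap``); fixed seed makes the draw reproducible.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no cells / state labels supplied")
    rng = np.random.default_rng(seed)
    rows = {}
    for state in sorted(map(str, pd.unique(labels))):
        idx = np.flatnonzero(labels.astype(str) == state)
        if len(idx) == 0:
            raise ValueError(f"state {state!r} has no cells")
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        rows[state] = expr[idx].mean(axis=0)
    return pd.DataFrame(rows, index=pd.Index([str(g) for g in genes])).T


def deconvolve(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    renormalize: bool = True,
) -> pd.DataFrame:
    """Estimate cell-state fractions per bulk sample by NNLS.

    ``bulk`` is genes x samples, ``signature`` states x genes; the gene
    spaces are intersected.  For each sample the non-negative f minimizing
    ||b - S^T f||^2 is found and (optionally) renormalized to sum to 1.
    Returns samples x states.
    """
    if signature.shape[0] < 2:
        raise ValueError("need at least 2 states to deconvolve")
    shared = [g for g in bulk.index if g in set(signature.columns)]
    if not shared:
        raise ValueError("no shared genes between bulk and signature")
    S = signature[shared].to_numpy(float)  # states x genes
    if np.linalg.matrix_rank(S) < S.shape[0]:
        warnings.warn("signature matrix is rank-deficient; fractions may be unstable")
    A = S.T  # genes x states
    out = {}
    for sample in bulk.columns:
        b = bulk.loc[shared, sample].to_numpy(float)
        f, _ = nnls(A, b)
        if renormalize:
            total = f.sum()
            f = f / total if total > 0 else np.full_like(f, 1.0 / len(f))
        out[sample] = f
    return pd.DataFrame(out, index=signature.index).T


def condition_enriched_state(
    fractions: pd.DataFrame,
    conditions,
    alpha: float = 0.05,
) -> dict[str, list[str]]:
    """Condition-enriched cell states.

    A state is enriched in condition c iff (1) its median fraction in c is
    strictly the greatest across conditions and (2) every pairwise Student
    t-test of c against each other condition has p < ``alpha``.  Degenerate
    (zero-variance) comparisons report p = 1 and never qualify.
    """
    conditions = pd.Series(np.asarray(conditions), index=fractions.index)
    groups = sorted(map(str, conditions.unique()))
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    for g in groups:
        if (conditions.astype(str) == g).sum() < 3:
            raise ValueError(f"condition {g!r} has fewer than 3 samples")
    enriched: dict[str, list[str]] = {g: [] for g in groups}
    for state in fractions.columns:
        by_group = {
            g: fractions.loc[conditions.astype(str) == g, state].to_numpy(float)
            for g in groups
        }
        medians = {g: float(np.median(v)) for g, v in by_group.items()}
        for g in groups:
            others = [h for h in groups if h != g]
            if not all(medians[g] > medians[h] for h in others):
                continue
            ok = True
            for h in others:
                a, b = by_group[g], by_group[h]
                if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
                    # t undefined: constant groups differ iff their means do
                    p = 1.0 if np.mean(a) == np.mean(b) else 0.0
                else:
                    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
                    if np.isnan(p):
                        p = 1.0
                if p >= alpha:
                    ok = False
                    break
            if ok:
                enriched[g].append(str(state))
    return enriched


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p.

    Zero-variance input yields (nan, nan) rather than an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ssgsea_score(expr: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score for one expression vector.

    Genes are ranked by expression (descending); the highest-expressed gene
    gets rank value N.  In-set genes are weighted by rank^alpha, and the
    score is the sum over all positions of the difference between the
    weighted in-set ECDF and the uniform out-of-set ECDF.  Being rank-based,
    the score is invariant to any strictly monotone transform of the
    expression values.
    """
    genes = expr.index.astype(str)
    in_set = np.asarray(genes.isin({str(g) for g in gene_set}))
    n = len(genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the expression vector")
    if n_in == n:
        raise ValueError("gene set covers every gene; score undefined")
    order = np.argsort(-expr.to_numpy(float), kind="stable")
    in_ordered = in_set[order]
    rank_values = np.arange(n, 0, -1, dtype=float)  # N..1 along descending expression
    w = np.abs(rank_values) ** alpha
    hit = np.where(in_ordered, w, 0.0)
    p_in = np.cumsum(hit) / hit.sum()
    miss = np.where(~in_ordered, 1.0, 0.0)
    p_out = np.cumsum(miss) / (n - n_in)
    return float(np.sum(p_in - p_out))


@dataclass
class GeneSetScoreTable:
    """ssGSEA scores per sample and gene set: raw, log2, min-max normalized."""

    raw: pd.DataFrame  # samples x gene sets
    log2: pd.DataFrame
    normalized: pd.DataFrame  # min-max per gene set, in [0, 1]


def ssgsea_table(
    expr: pd.DataFrame,
    gene_sets: dict,
    alpha: float = 0.25,
    normalization: str = "minmax",
) -> GeneSetScoreTable:
    """Score every sample (column of genes x samples ``expr``) against every
    gene set; log2-transform (scores shifted positive first when needed) and
    normalize per gene set (min-max by default, z-score optional)."""
    raw = pd.DataFrame(
        {
            name: {s: ssgsea_score(expr[s], genes, alpha=alpha) for s in expr.columns}
            for name, genes in gene_sets.items()
        }
    )
    shifted = raw.copy()
    for c in shifted.columns:
        lo = shifted[c].min()
        if lo <= 0:
            shifted[c] = shifted[c] - lo + 1.0
    log2 = np.log2(shifted)
    if normalization == "minmax":
        rng = log2.max() - log2.min()
        rng = rng.replace(0, 1.0)
        normalized = (log2 - log2.min()) / rng
    elif normalization == "zscore":
        sd = log2.std(ddof=0).replace(0, 1.0)
        normalized = (log2 - log2.mean()) / sd
    else:
        raise ValueError("normalization must be 'minmax' or 'zscore'")
    return GeneSetScoreTable(raw=raw, log2=log2, normalized=normalized)


def pairwise_letter_display(
    values: pd.Series, groups, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """All pairwise pooled t-tests plus a compact letter display.

    Letters are assigned with the insert-and-absorb algorithm: groups sharing
    no letter differ at p < ``alpha``.  Returns (pairwise table, letters).
    """
    groups = pd.Series(np.asarray(groups), index=values.index).astype(str)
    names = sorted(groups.unique())
    pairs = []
    differ = set()
    for a, b in itertools.combinations(names, 2):
        x = values[groups == a].to_numpy(float)
        y = values[groups == b].to_numpy(float)
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            p = 1.0 if np.mean(x) == np.mean(y) else 0.0
        else:
            p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
            if np.isnan(p):
                p = 1.0
        pairs.append({"a": a, "b": b, "p": p})
        if p < alpha:
            differ.add((a, b))

    # insert-and-absorb: maintain letter groups (sets of mutually compatible names)
    letters: list[set] = []
    for name in names:
        placed = False
        for group in letters:
            if all((min(name, m), max(name, m)) not in differ for m in group):
                group.add(name)
                placed = True
        if not placed:
            letters.append({name})
    # absorb letter groups fully contained in another
    letters = [g for i, g in enumerate(letters)
               if not any(i != j and g < h for j, h in enumerate(letters))]
    assignment = {name: "" for name in names}
    for i, group in enumerate(letters):
        ch = chr(ord("a") + i)
        for name in sorted(group):
            assignment[name] += ch
    return pd.DataFrame(pairs), assignment


def signal_to_noise(expr: pd.DataFrame, labels, target: str) -> pd.Series:
    """Classic GSEA signal-to-noise ranking statistic, target class vs rest.

    (mu_t - mu_r) / (sd_t + sd_r) with each sd floored at 0.2 * |mean| (and
    at 0.2 when the mean is 0), per the statistic's conventional guard
    against vanishing variance.
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns).astype(str)
    a = expr.loc[:, labels == str(target)].to_numpy(float)
    b = expr.loc[:, labels != str(target)].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per class")
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sd_a = np.maximum(sd_a, np.where(mu_a != 0, 0.2 * np.abs(mu_a), 0.2))
    sd_b = np.maximum(sd_b, np.where(mu_b != 0, 0.2 * np.abs(mu_b), 0.2))
    return pd.Series((mu_a - mu_b) / (sd_a + sd_b), index=expr.index)


def gsea_leading_edge(
    ranking: pd.Series, gene_set, exponent: float = 1.0
) -> tuple[float, list[str], np.ndarray]:
    """Classic weighted Kolmogorov-Smirnov GSEA on a ranked gene list.

    ``ranking`` maps gene -> ranking statistic (e.g. signal-to-noise); genes
    are ordered descending.  Hits increment the running sum by
    |stat|^exponent (normalized); misses decrement by 1/(N - |set|).  The
    enrichment score is the maximal deviation from zero; the leading edge is
    the in-set genes at or before the peak (positive ES) or at or after the
    trough (negative ES).  Returns (ES, leading-edge genes, running sum).
    """
    genes = ranking.index.astype(str)
    members = {str(g) for g in gene_set}
    in_set = np.asarray(genes.isin(members))
    if not in_set.any():
        raise ValueError("gene set absent from the ranking")
    order = np.argsort(-ranking.to_numpy(float), kind="stable")
    stat = ranking.to_numpy(float)[order]
    hits = in_set[order]
    names = np.asarray(genes)[order]
    n = len(names)
    n_in = int(hits.sum())
    w = np.abs(stat) ** exponent
    w_hit = np.where(hits, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:
        w_hit = hits.astype(float)
        denom = w_hit.sum()
    p_hit = np.cumsum(w_hit) / denom
    p_miss = np.cumsum(np.where(hits, 0.0, 1.0)) / max(n - n_in, 1)
    running = p_hit - p_miss
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        leading = [str(g) for g, h in zip(names[: i_max + 1], hits[: i_max + 1]) if h]
    else:
        leading = [str(g) for g, h in zip(names[i_min:], hits[i_min:]) if h]
    return float(es), leading, running


def cms4_protein_enrichment(
    intensities: pd.DataFrame,
    subtypes,
    target: str = "CMS4",
    per_subtype: bool = False,
) -> list[str]:
    """Proteins whose mean intensity in the target subtype strictly exceeds
    the mean over pooled non-target samples (default), or every other
    subtype's mean with ``per_subtype=True``."""
    subtypes = pd.Series(np.asarray(subtypes), index=intensities.columns).astype(str)
    t_cols = subtypes.index[subtypes == target]
    o_cols = subtypes.index[subtypes != target]
    if len(t_cols) == 0:
        raise ValueError(f"no {target} samples")
    if len(o_cols) == 0:
        raise ValueError("no non-target samples")
    t_mean = intensities[t_cols].mean(axis=1)
    if per_subtype:
        keep = pd.Series(True, index=intensities.index)
        for sub in subtypes[subtypes != target].unique():
            cols = subtypes.index[subtypes == sub]
            keep &= t_mean > intensities[cols].mean(axis=1)
    else:
        keep = t_mean > intensities[o_cols].mean(axis=1)
    return intensities.index[keep].astype(str).tolist()


def intersect_signature(
    enriched_genes, enriched_proteins, state_of_gene: dict | None = None
) -> pd.DataFrame:
    """Exact intersection of gene- and protein-level enriched symbol sets,
    labeled by the fibroblast state each molecule is associated with (from a
    cell-matrisome database mapping, when provided)."""
    genes = {str(g) for g in enriched_genes}
    prots = {str(p) for p in enriched_proteins}
    molecules = sorted(genes & prots)
    states = [
        (state_of_gene or {}).get(m, "unassigned") for m in molecules
    ]
    return pd.DataFrame({"molecule": molecules, "state": states}).set_index("molecule")


def multi_gene_score(expr: pd.DataFrame, gene_list) -> pd.Series:
    """Per-sample normalized score of a gene list: min-max normalize each
    gene across samples, then average over genes.  Output lies in [0, 1];
    constant genes contribute 0 (with a warning)."""
    genes = [str(g) for g in gene_list]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression: {missing}")
    sub = expr.loc[genes].to_numpy(float)
    lo = sub.min(axis=1, keepdims=True)
    hi = sub.max(axis=1, keepdims=True)
    span = hi - lo
    if (span == 0).any():
        warnings.warn("constant gene(s) contribute 0 to the multi-gene score")
    span[span == 0] = 1.0
    norm = (sub - lo) / span
    return pd.Series(norm.mean(axis=0), index=expr.columns)
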