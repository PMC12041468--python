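"""TMT proteomics: reference-channel QC, normalization, matrisome composition and
differential-protein analysis.

The quantitative unit is a protein-level reporter-ion intensity table
(proteins x samples).  Each TMT batch carries three pooled-reference channels
labeled at a 0.5:1:2 ratio, so the per-protein log2 ratios 131N/131C,
131C/130N and 131N/130N concentrate around 1, 1 and 2; deviations from the
batch median are used for outlier truncation.  Normalization proceeds in two
steps: per-column median centering on the log2 scale (re-centered to the mean
of the original column medians), followed by inter-sample normalization
against a designated reference column.  Composition is summarised as relative
percent composition (RPC): each protein's intensity divided by the summed
intensity of all detected proteins in that sample, x100.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

CORE_CATEGORIES = ("COL", "GLY", "PRO")
ASSOCIATED_CATEGORIES = ("REG", "AFF", "SEC")
REFERENCE_CHANNELS = ("130N", "131C", "131N")
REFERENCE_WEIGHTS = (0.5, 1.0, 2.0)
#: selection thresholds: |log2 FC| > 0.5 (fold-change > sqrt(2)), BH q < 0.01
DEP_LOG2FC_THRESHOLD = 0.5
DEP_ALPHA = 0.01

RATIO_NAMES = ("131N/131C", "131C/130N", "131N/130N")
#: log2 of the nominal reference-channel ratios 2/1, 1/0.5 and 2/0.5
EXPECTED_LOG2_RATIOS = (1.0, 1.0, 2.0)


@dataclass
class IntensityTable:
    """Proteins x samples positive intensities with sample metadata.

    ``groups`` maps each sample to ``NAT``, ``Tumor`` or ``Reference``;
    ``batches`` maps each sample to its TMT batch.  ``scale`` tracks whether
    values are raw, log2 or normalized.
    """

    data: pd.DataFrame
    groups: pd.Series
    batches: pd.Series
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in {"raw", "log2", "normalized"}:
            raise ValueError(f"unknown scale {self.scale!r}")
        missing = set(self.data.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group metadata: {sorted(missing)[:5]}")
        if self.data.isna().any().any():
            raise ValueError("intensity table contains missing values")
        if self.scale == "raw" and (self.data.values < 0).any():
            raise ValueError("negative raw intensities; remove them before use")
        if self.scale == "normalized" and (self.data.values <= 0).any():
            raise ValueError(
                "non-positive normalized intensities; floor or remove them "
                "before use (see normalize_intensities(floor=...))"
            )

    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]


@dataclass
class ChannelDesign:
    """Reference-channel layout: per batch, the three pooled-control channels
    (nominal weights 0.5, 1, 2) plus the designated inter-sample reference
    sample used in normalization step 2."""

    table: pd.DataFrame  # columns: batch, channel, sample_id, weight
    reference_sample: str

    def __post_init__(self) -> None:
        required = {"batch", "channel", "sample_id", "weight"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        for batch, sub in self.table.groupby("batch"):
            if len(sub) != 3:
                raise ValueError(f"batch {batch}: expected exactly 3 reference channels")
            ws = sub["weight"].sort_values().tolist()
            if not all(a < b for a, b in zip(ws, ws[1:])):
                raise ValueError(f"batch {batch}: reference weights must be strictly increasing")
        if self.reference_sample not in set(self.table["sample_id"]):
            raise ValueError(f"reference sample {self.reference_sample!r} not a reference channel")

    def batch_channels(self, batch) -> dict[str, str]:
        """Map channel name -> sample id for one batch, ordered by weight."""
        sub = self.table[self.table["batch"] == batch].sort_values("weight")
        return dict(zip(sub["channel"], sub["sample_id"]))

    @property
    def batches(self) -> list:
        return sorted(self.table["batch"].unique().tolist())


@dataclass
class MatrisomeAnnotation:
    """Gene symbol -> matrisome division and category.

    Core matrisome: collagens (COL), ECM glycoproteins (GLY), proteoglycans
    (PRO); matrisome-associated: ECM regulators (REG), ECM-affiliated (AFF),
    secreted factors (SEC).  Symbols are matched case-insensitively; anything
    unmatched is non-matrisome.
    """

    table: pd.DataFrame  # index: upper-case gene symbol; columns: division, category

    _CORE = set(CORE_CATEGORIES)
    _ASSOC = set(ASSOCIATED_CATEGORIES)

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("empty matrisome annotation")
        self.table = self.table.copy()
        self.table.index = self.table.index.str.upper()
        for sym, row in self.table.iterrows():
            div, cat = row["division"], row["category"]
            if div == "core" and cat not in self._CORE:
                raise ValueError(f"{sym}: core division requires category in {sorted(self._CORE)}")
            if div == "associated" and cat not in self._ASSOC:
                raise ValueError(
                    f"{sym}: associated division requires category in {sorted(self._ASSOC)}"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MatrisomeAnnotation":
        """Build from a Human-Matrisome-Database-style frame with columns
        'Gene Symbol', 'Division', 'Category' (division text containing 'core'
        or 'associated' is recognised)."""
        sym = frame["Gene Symbol"].astype(str).str.upper()
        div_raw = frame["Division"].astype(str).str.lower()
        division = np.where(
            div_raw.str.contains("core"),
            "core",
            np.where(div_raw.str.contains("associated"), "associated", "non-matrisome"),
        )
        table = pd.DataFrame(
            {"division": division, "category": frame["Category"].astype(str).values},
            index=pd.Index(sym, name="gene"),
        )
        return cls(table)

    def lookup(self, symbol: str) -> tuple[str, str]:
        key = str(symbol).upper()
        if key in self.table.index:
            row = self.table.loc[key]
            return str(row["division"]), str(row["category"])
        return "non-matrisome", "none"

    def is_matrisome(self, symbol: str) -> bool:
        return self.lookup(symbol)[0] != "non-matrisome"

    def matrisome_genes(self) -> set[str]:
        return set(self.table.index[self.table["division"] != "non-matrisome"])


@dataclass
class ReferenceQC:
    """Per-batch reference-channel log2 ratios, summary stats and outlier flags."""

    ratios: dict  # batch -> DataFrame (proteins x RATIO_NAMES), log2 scale
    summary: pd.DataFrame  # rows (batch, ratio): median, sd
    outliers: pd.DataFrame  # proteins x batches, bool


@dataclass
class RPCTable:
    """Relative percent composition per sample, with category roll-up."""

    protein_pct: pd.DataFrame  # proteins x samples, sums to 100 per sample
    category_pct: pd.DataFrame  # categories x samples
    protein_category: pd.Series  # protein -> matrisome category ('none' otherwise)

    def __post_init__(self) -> None:
        sums = self.protein_pct.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("per-sample RPC must sum to 100")


def reference_ratio_qc(table: IntensityTable, design: ChannelDesign, alpha: float = 0.05) -> ReferenceQC:
    """Compute per-protein log2 reference-channel ratios and flag outliers.

    For each batch the three pooled-control columns (weights 0.5, 1, 2) give
    log2 ratios expected near (1, 1, 2).  Each ratio is standardized against
    its batch median and scale; two-sided normal p-values are truncated with
    Benjamini-Hochberg at ``alpha`` and failing proteins flagged.
    """
    ratios: dict = {}
    rows = []
    flags = pd.DataFrame(False, index=table.protein_ids, columns=design.batches)
    for batch in design.batches:
        channels = design.batch_channels(batch)
        missing = [s for s in channels.values() if s not in table.data.columns]
        if missing:
            raise KeyError(f"batch {batch}: reference channel column(s) {missing} missing")
        ordered = list(channels.values())  # weight order 0.5, 1, 2
        low, mid, high = (np.log2(table.data[s].values) for s in ordered)
        mat = pd.DataFrame(
            {"131N/131C": high - mid, "131C/130N": mid - low, "131N/130N": high - low},
            index=table.protein_ids,
        )
        ratios[batch] = mat
        pvals = np.ones((len(mat), 3))
        for j, name in enumerate(RATIO_NAMES):
            x = mat[name].values
            med = float(np.median(x))
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            rows.append({"batch": batch, "ratio": name, "median": med, "sd": sd})
            if sd > 0:
                z = (x - med) / sd
                pvals[:, j] = 2.0 * stats.norm.sf(np.abs(z))
        rejected = multipletests(pvals.ravel(), alpha=alpha, method="fdr_bh")[0].reshape(pvals.shape)
        flags[batch] = rejected.any(axis=1)
    summary = pd.DataFrame(rows).set_index(["batch", "ratio"])
    return ReferenceQC(ratios=ratios, summary=summary, outliers=flags)


def median_center(table: IntensityTable, floor: float | str | None = "auto") -> np.ndarray:
    """Normalization step 1: log2, subtract each column's median, add back the
    mean of the original column medians, exponentiate.  After this, every
    column has the same log2 median (the mean of the originals).

    Zeros are floored at ``floor`` (``"auto"`` = half the smallest positive
    value); ``floor=None`` makes zeros an error.  Negatives always error.
    """
    values = table.data.to_numpy(dtype=float, copy=True)
    if (values < 0).any():
        raise ValueError("negative intensities cannot be normalized; remove them")
    if (values == 0).any():
        if floor is None:
            raise ValueError(
                "zero intensities present; pass floor='auto' (half the smallest "
                "positive value) or a positive float, or remove the rows"
            )
        fl = values[values > 0].min() / 2.0 if floor == "auto" else float(floor)
        values[values == 0] = fl
    log2v = np.log2(values)
    col_medians = np.median(log2v, axis=0)
    return np.exp2(log2v - col_medians + col_medians.mean())


def normalize_intensities(
    table: IntensityTable,
    design: ChannelDesign,
    floor: float | str | None = "auto",
) -> IntensityTable:
    """Two-step normalization of a raw intensity table.

    Step 1 removes per-column systematic bias: log2, subtract each column's
    median, add back the mean of the original column medians, exponentiate.
    Step 2 normalizes across samples: divide each protein by its value in the
    designated reference column, then multiply by that column's average
    normalized intensity (a scalar).

    Zeros are floored at ``floor`` (``"auto"`` = half the smallest positive
    value) before log2; ``floor=None`` makes zeros an error.  Negative values
    are always an error.
    """
    if table.scale != "raw":
        raise ValueError("normalize_intensities expects a raw-scale table")
    step1 = median_center(table, floor=floor)

    ref = design.reference_sample
    if ref not in table.data.columns:
        raise KeyError(f"reference sample {ref!r} not in table")
    ref_col = step1[:, table.data.columns.get_loc(ref)].copy()
    if (ref_col == 0).any():
        raise ValueError("reference column contains zeros after step 1")
    relative = step1 / ref_col[:, None]
    normalized = relative * ref_col.mean()

    out = pd.DataFrame(normalized, index=table.protein_ids, columns=table.sample_ids)
    return replace(table, data=out, scale="normalized")


def annotate_matrisome(protein_ids, annotation: MatrisomeAnnotation) -> pd.DataFrame:
    """Assign each identifier a matrisome division/category (case-insensitive);
    unmatched identifiers are non-matrisome."""
    rows = [annotation.lookup(p) for p in protein_ids]
    return pd.DataFrame(rows, index=pd.Index(protein_ids), columns=["division", "category"])


def compute_rpc(
    table: IntensityTable,
    annotation: MatrisomeAnnotation | None = None,
    allow_raw: bool = False,
) -> RPCTable:
    """Relative percent composition: intensity / per-sample total x 100,
    with a per-category roll-up when an annotation is supplied."""
    if table.scale == "log2":
        raise ValueError("RPC requires linear-scale intensities")
    if table.scale == "raw" and not allow_raw:
        raise ValueError("table is raw; normalize first or pass allow_raw=True")
    totals = table.data.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    pct = table.data / totals * 100.0

    if annotation is not None:
        ann = annotate_matrisome(table.protein_ids, annotation)
        cats = ann["category"]
    else:
        cats = pd.Series("none", index=table.protein_ids)
    category_pct = pct.groupby(cats).sum()
    return RPCTable(protein_pct=pct, category_pct=category_pct, protein_category=cats)


def category_diff_test(rpc: RPCTable, groups: pd.Series, group_a: str = "NAT", group_b: str = "Tumor") -> pd.DataFrame:
    """Two-sided pooled-variance (Student) t-test of per-category RPC between
    two sample groups.  Categories with zero pooled variance get NaN p."""
    a_cols = [s for s in rpc.category_pct.columns if groups.get(s) == group_a]
    b_cols = [s for s in rpc.category_pct.columns if groups.get(s) == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 samples per group")
    a = rpc.category_pct[a_cols].to_numpy(float)
    b = rpc.category_pct[b_cols].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    return pd.DataFrame({"t": t, "p": p}, index=rpc.category_pct.index)


def dep_analysis(
    table: IntensityTable,
    group_a: str = "NAT",
    group_b: str = "Tumor",
    log2fc_threshold: float = DEP_LOG2FC_THRESHOLD,
    alpha: float = DEP_ALPHA,
) -> pd.DataFrame:
    """Differential-protein analysis: Welch's t on log2 intensities with
    Benjamini-Hochberg correction across all tested proteins.

    Positive log2 fold-change means enrichment in ``group_b`` (Tumor by
    default).  Selection: |log2 FC| > ``log2fc_threshold`` (fold-change >
    sqrt(2) at the default) and adjusted p < ``alpha``.
    Returns a frame with log2fc, p, q, selected, direction.
    """
    if table.scale != "normalized":
        raise ValueError("dep_analysis expects a normalized table")
    a_cols = table.samples_in_group(group_a)
    b_cols = table.samples_in_group(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 samples per group for Welch's t-test")
    a = np.log2(table.data[a_cols].to_numpy(float))
    b = np.log2(table.data[b_cols].to_numpy(float))
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    selected = (np.abs(log2fc) > log2fc_threshold) & (q < alpha)
    direction = np.where(log2fc > 0, f"{group_b}-enriched", f"{group_a}-enriched")
    direction = np.where(selected, direction, "ns")
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "q": q, "selected": selected, "direction": direction},
        index=table.protein_ids,
    )


def top_composition(
    rpc: RPCTable,
    samples: list[str],
    n: int = 20,
    matrisome_only: bool = True,
) -> pd.Series:
    """Top-``n`` proteins by mean RPC over ``samples`` (descending); ties are
    broken lexicographically by protein id.  With ``matrisome_only`` the
    ranking is restricted to annotated matrisome proteins."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mean_rpc = rpc.protein_pct[samples].mean(axis=1)
    if matrisome_only:
        mean_rpc = mean_rpc[rpc.protein_category != "none"]
    order = sorted(mean_rpc.index, key=lambda g: (-mean_rpc[g], str(g)))
    return mean_rpc.loc[order[:n]]


def coverage_count(rpc: RPCTable, samples: list[str], fraction: float = 0.9) -> int:
    """Minimal number of proteins whose summed mean RPC reaches
    ``fraction`` x 100, taking proteins greedily in descending mean RPC."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mean_rpc = rpc.protein_pct[samples].mean(axis=1)
    mean_rpc = mean_rpc[mean_rpc > 0]
    ordered = np.sort(mean_rpc.values)[::-1]
    csum = np.cumsum(ordered)
    target = fraction * mean_rpc.sum() if fraction == 1.0 else fraction * 100.0
    # mean RPC sums to 100 across all proteins, so the two targets coincide
    idx = int(np.searchsorted(csum, target - 1e-12) + 1)
    return min(idx, len(ordered))


def ora_enrichment(query_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Over-representation analysis: one-sided hypergeometric tail per gene
    set with BH correction across sets.

    ``query_genes`` must be a subset of ``universe``; gene sets are
    intersected with the universe before testing.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        in_univ = set(genes) & universe
        k = len(query & in_univ)
        # P(X >= k) with N=|universe|, K=|set|, n=|query|
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_univ), len(query)))
        rows.append({"set": name, "set_size": len(in_univ), "overlap": k, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"].values, method="fdr_bh")[1] if len(out) else []
    return out


@dataclass
class ProfileStructure:
    pca_coords: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    distances: pd.DataFrame  # samples x samples, Euclidean
    linkage_matrix: np.ndarray  # scipy average-linkage tree over samples


def profile_structure(
    data: pd.DataFrame,
    annotation: MatrisomeAnnotation | None = None,
    matrisome_only: bool = True,
    n_components: int = 2,
) -> ProfileStructure:
    """Sample-level structure of a (normalized) intensity table: per-protein
    z-scaling, PCA, pairwise Euclidean distances and average-linkage
    hierarchical clustering.  Optionally restricted to matrisome proteins."""
    if data.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    mat = data
    if matrisome_only and annotation is not None:
        ann = annotate_matrisome(data.index, annotation)
        mat = data.loc[ann["division"] != "non-matrisome"]
    x = np.log2(mat.to_numpy(float)) if (mat.values > 0).all() else mat.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    samples = mat.columns
    n_comp = min(n_components, len(samples) - 1, z.shape[0])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(z.T)
    dvec = pdist(z.T, metric="euclidean")
    dmat = pd.DataFrame(squareform(dvec), index=samples, columns=samples)
    tree = linkage(dvec, method="average")
    return ProfileStructure(
        pca_coords=pd.DataFrame(coords, index=samples, columns=[f"PC{i+1}" for i in range(n_comp)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        distances=dmat,
        linkage_matrix=tree,
    )
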