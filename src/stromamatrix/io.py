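"""Plain-text readers and writers for every pipeline input and output.

Tabular data travel as TSV (proteins/genes as rows, samples as columns),
single-cell counts as Matrix Market MTX plus barcodes/features TSV, gene
sets as GMT, and metadata/truth/config as JSON or YAML sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

import anndata as ad

from .proteomics import ChannelDesign, IntensityTable, MatrisomeAnnotation


# ---- TMT intensity tables -------------------------------------------------

def write_intensity_tsv(table: IntensityTable, path) -> None:
    table.data.to_csv(path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": table.sample_ids,
         "group": [table.groups[s] for s in table.sample_ids],
         "batch": [table.batches[s] for s in table.sample_ids]}
    )
    meta.to_csv(Path(path).with_suffix(".meta.tsv"), sep="\t", index=False)


def read_intensity_tsv(path, meta_path=None, scale: str = "raw") -> IntensityTable:
    data = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = meta_path or Path(path).with_suffix(".meta.tsv")
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    return IntensityTable(
        data=data,
        groups=meta["group"],
        batches=meta["batch"],
        scale=scale,
    )


def write_design_tsv(design: ChannelDesign, path) -> None:
    out = design.table.copy()
    out["reference_sample"] = design.reference_sample
    out.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> ChannelDesign:
    table = pd.read_csv(path, sep="\t")
    ref = str(table["reference_sample"].iloc[0]) if "reference_sample" in table else None
    cols = [c for c in table.columns if c != "reference_sample"]
    if ref is None:
        first_batch = table["batch"].min()
        sub = table[table["batch"] == first_batch].sort_values("weight")
        ref = str(sub["sample_id"].iloc[0])
    return ChannelDesign(table=table[cols], reference_sample=ref)


# ---- matrisome annotation and gene sets -----------------------------------

def read_matrisome_csv(path) -> MatrisomeAnnotation:
    """Human-Matrisome-Database-style CSV with columns Gene Symbol /
    Division / Category."""
    return MatrisomeAnnotation.from_frame(pd.read_csv(path))


def write_matrisome_csv(annotation: MatrisomeAnnotation, path) -> None:
    div_text = annotation.table["division"].map(
        {"core": "Core matrisome", "associated": "Matrisome-associated"}
    ).fillna("Non-matrisome")
    out = pd.DataFrame(
        {"Gene Symbol": annotation.table.index,
         "Division": div_text.values,
         "Category": annotation.table["category"].values}
    )
    out.to_csv(path, index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: one set per line, name <tab> description <tab> genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


# ---- single-cell counts ----------------------------------------------------

def write_counts_mtx(adata: ad.AnnData, prefix) -> None:
    """Write counts as <prefix>.mtx with <prefix>.barcodes.tsv /
    <prefix>.features.tsv / <prefix>.obs.tsv sidecars."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(np.asarray(adata.X)))
    pd.Series(adata.obs_names).to_csv(
        prefix.parent / f"{prefix.name}.barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        prefix.parent / f"{prefix.name}.features.tsv", sep="\t", index=False, header=False
    )
    adata.obs.to_csv(prefix.parent / f"{prefix.name}.obs.tsv", sep="\t")


def read_counts_mtx(prefix) -> ad.AnnData:
    prefix = Path(prefix)
    x = np.asarray(mmread(str(prefix.with_suffix(".mtx"))).todense())
    barcodes = pd.read_csv(
        prefix.parent / f"{prefix.name}.barcodes.tsv", sep="\t", header=None
    )[0].astype(str)
    features = pd.read_csv(
        prefix.parent / f"{prefix.name}.features.tsv", sep="\t", header=None
    )[0].astype(str)
    obs_path = prefix.parent / f"{prefix.name}.obs.tsv"
    obs = (
        pd.read_csv(obs_path, sep="\t", index_col=0)
        if obs_path.exists()
        else pd.DataFrame(index=barcodes)
    )
    obs.index = barcodes
    return ad.AnnData(
        X=x.astype(np.int64), obs=obs, var=pd.DataFrame(index=pd.Index(features, name="gene"))
    )


# ---- generic tables --------------------------------------------------------

def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
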