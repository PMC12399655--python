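"""Plain-text input/output for every pipeline artifact.

Expression matrices travel as TSV with genes as rows and samples as
columns; sample metadata, survival tables, heterogeneity tables, DE
tables and truth tables are TSV; cell count matrices use MatrixMarket
plus a cell-metadata TSV; fitted signature models serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import SignatureModel

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_survival",
    "write_survival",
    "read_cells",
    "write_cells",
    "read_gene_list",
    "write_gene_list",
    "save_signature",
    "load_signature",
]


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_survival(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index_label="sample_id")


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_cells(adata: ad.AnnData, mtx_path, meta_path, genes_path=None) -> None:
    """Counts to MatrixMarket (cells x genes) + metadata TSV (+ gene list)."""
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(np.asarray(adata.X)))
    adata.obs.to_csv(meta_path, sep="\t", index_label="cell_id")
    if genes_path is not None:
        write_gene_list(list(adata.var_names), genes_path)


def read_cells(mtx_path, meta_path, genes_path=None) -> ad.AnnData:
    x = np.asarray(spio.mmread(str(mtx_path)).todense())
    obs = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
    var = None
    if genes_path is not None:
        var = pd.DataFrame(index=pd.Index(read_gene_list(genes_path), name="gene"))
    return ad.AnnData(X=x, obs=obs, var=var)


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_gene_list(path) -> list[str]:
    return [g for g in Path(path).read_text().splitlines() if g.strip()]


def save_signature(model: SignatureModel, path) -> None:
    payload = {
        "genes": model.genes,
        "beta": model.beta.tolist(),
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "train_median_score": model.train_median_score,
        "selection_frequencies": (
            None
            if model.selection_frequencies is None
            else {
                str(k): float(v)
                for k, v in model.selection_frequencies.items()
            }
        ),
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_signature(path) -> SignatureModel:
    payload = json.loads(Path(path).read_text())
    genes = payload["genes"]
    idx = pd.Index(genes, name="gene")
    freqs = payload.get("selection_frequencies")
    return SignatureModel(
        genes=genes,
        beta=pd.Series(payload["beta"], index=idx),
        mean=pd.Series(payload["mean"], index=idx),
        sd=pd.Series(payload["sd"], index=idx),
        train_median_score=payload["train_median_score"],
        selection_frequencies=None if freqs is None else pd.Series(freqs),
        meta=payload.get("meta", {}),
    )
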