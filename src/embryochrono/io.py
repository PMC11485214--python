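"""On-disk layout for cohorts: sparse MTX counts plus TSV sidecars.

A cohort directory holds ``matrix.mtx`` (genes x cells, Matrix Market),
``genes.tsv`` (one row per gene), ``cells.tsv`` (cell, embryo, condition and
any truth columns) and ``embryos.tsv``. All tables are tab-separated with a
header; gene identifiers are plain case-sensitive symbols.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_cohort(adata: ad.AnnData, outdir: str) -> None:
    """Write an AnnData cohort (cells x genes) to a cohort directory."""
    os.makedirs(outdir, exist_ok=True)
    X = sp.csc_matrix(adata.X.T)  # genes x cells on disk
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), X, field="integer")
    genes = adata.var.reset_index().rename(columns={"index": "gene"})
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index=False)
    cells = adata.obs.reset_index().rename(columns={"index": "cell"})
    cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)
    if "embryos" in adata.uns:
        pd.DataFrame(adata.uns["embryos"]).to_csv(
            os.path.join(outdir, "embryos.tsv"), sep="\t", index=False
        )


def read_cohort(indir: str) -> ad.AnnData:
    """Read a cohort directory back into AnnData (cells x genes, integer CSR)."""
    X = scipy.io.mmread(os.path.join(indir, "matrix.mtx"))
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")
    cells = pd.read_csv(os.path.join(indir, "cells.tsv"), sep="\t")
    adata = ad.AnnData(
        X=sp.csr_matrix(X.T, dtype=np.int64),
        obs=cells.set_index("cell"),
        var=genes.set_index("gene"),
    )
    emb_path = os.path.join(indir, "embryos.tsv")
    if os.path.exists(emb_path):
        adata.uns["embryos"] = pd.read_csv(emb_path, sep="\t")
    return adata


def counts_matrix(adata: ad.AnnData) -> sp.csr_matrix:
    """Return the raw UMI counts as CSR, whatever the stored backing is."""
    X = adata.X
    if sp.issparse(X):
        return sp.csr_matrix(X)
    return sp.csr_matrix(np.asarray(X))
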