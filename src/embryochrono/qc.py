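"""Cell quality control: count-depth filters and an artificial-doublet score.

``filter_cells`` applies the standard UMI-depth window (cells with fewer than
2,000 or more than 30,000 counts are removed) plus an optional
mitochondrial:ribosomal count-ratio rule. ``doublet_scores`` computes a pANN
score: artificial doublets are synthesized by summing random cell pairs, real
and artificial cells are embedded in a PCA space of log-normalized expression,
and each real cell is scored by the fraction of artificial cells among its
nearest neighbours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import counts_matrix


@dataclass
class QCParams:
    min_counts: int = 2000
    max_counts: int = 30000
    mito_ribo_ratio_max: float = 1.0
    mito_genes: list[str] = field(default_factory=list)
    ribo_genes: list[str] = field(default_factory=list)
    pN: float = 0.25
    pK: float = 0.02
    pANN_threshold: float = 0.2
    n_pcs: int = 30

    def validate(self) -> None:
        if not (0 < self.min_counts < self.max_counts):
            raise ValueError("need 0 < min_counts < max_counts")
        if not (0 < self.pN < 1):
            raise ValueError("pN must be in (0, 1)")
        if not (0 < self.pK < 1):
            raise ValueError("pK must be in (0, 1)")


def filter_cells(adata: ad.AnnData, params: QCParams) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply depth and mito:ribo filters; return kept cells plus a report.

    Boundaries are inclusive for retention (removal rules are strict
    "less than" / "more than"). The report lists every cell with pass/fail and
    the first failing rule in the fixed order low, high, ratio. The ratio rule
    is skipped when either gene list is empty.
    """
    params.validate()
    if adata.n_obs == 0:
        raise ValueError("empty count matrix")
    X = counts_matrix(adata)
    totals = np.asarray(X.sum(axis=1)).ravel()
    reason = np.array([""] * adata.n_obs, dtype=object)
    low = totals < params.min_counts
    high = totals > params.max_counts
    reason[high] = "high"
    reason[low] = "low"

    if params.mito_genes and params.ribo_genes:
        mito_idx = adata.var_names.get_indexer(
            [g for g in params.mito_genes if g in adata.var_names]
        )
        ribo_idx = adata.var_names.get_indexer(
            [g for g in params.ribo_genes if g in adata.var_names]
        )
        mito = np.asarray(X[:, mito_idx].sum(axis=1)).ravel()
        ribo = np.asarray(X[:, ribo_idx].sum(axis=1)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ribo > 0, mito / np.maximum(ribo, 1), np.inf)
        bad_ratio = (ratio > params.mito_ribo_ratio_max) & (reason == "")
        reason[bad_ratio] = "ratio"

    keep = reason == ""
    report = pd.DataFrame(
        {"total_counts": totals, "pass": keep, "reason": reason}, index=adata.obs_names
    )
    if not keep.any():
        warnings.warn("all cells removed by QC filters")
    return adata[keep].copy(), report


def _log_cpm10(X: sp.csr_matrix) -> np.ndarray:
    """log2(1 + CPM/10): the fixed embedding transform for doublet scoring."""
    totals = np.asarray(X.sum(axis=1)).ravel()
    totals = np.maximum(totals, 1)
    dense = np.asarray(X.todense(), dtype=float)
    return np.log2(1.0 + dense / totals[:, None] * 1e5)


def doublet_scores(
    adata: ad.AnnData, params: QCParams, seed: int = 0, permute_labels: bool = False
) -> pd.Series:
    """pANN doublet score per cell.

    ``round(pN * n)`` artificial doublets are synthesized by summing counts of
    random cell pairs; real and artificial cells are embedded by PCA (top
    ``n_pcs`` components of log2(1 + CPM/10)); each real cell's score is the
    fraction of artificial cells among its ``round(pK * (n_real + n_art))``
    nearest neighbours. Deterministic given the seed; invariant (up to the
    permutation) to cell order.

    ``permute_labels=True`` scores against a random relabelling of which
    joint cells count as artificial — the exchangeability null whose expected
    mean is ``pN/(1+pN)`` — for calibration checks.
    """
    params.validate()
    n = adata.n_obs
    if n < 10:
        raise ValueError("need at least 10 cells for doublet scoring")
    X = counts_matrix(adata)
    rng = np.random.default_rng(seed)
    n_art = int(round(params.pN * n))
    # draw pairs in a cell-order-invariant way: sort cells by name first
    order = np.argsort(np.asarray(adata.obs_names))
    pairs = rng.integers(0, n, size=(n_art, 2))
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 1] + 1) % n
    art = sp.vstack([X[order[pairs[:, 0]]] + X[order[pairs[:, 1]]]], format="csr")

    joint = sp.vstack([X, art], format="csr")
    emb = _log_cpm10(joint)
    n_pcs = min(params.n_pcs, emb.shape[1], joint.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(emb)

    k = int(round(params.pK * (n + n_art)))
    if k < 1:
        raise ValueError("pK neighbourhood smaller than one cell")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    idx = idx[:, 1:]  # drop self
    if permute_labels:
        labels = np.zeros(n + n_art, dtype=bool)
        labels[rng.choice(n + n_art, size=n_art, replace=False)] = True
        pann = labels[idx].mean(axis=1)
    else:
        pann = (idx >= n).mean(axis=1)
    return pd.Series(pann, index=adata.obs_names, name="pANN")
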