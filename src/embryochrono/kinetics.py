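"""Lineage gene programs, single-cell scores and principal-curve pseudotime.

The lineage analysis selects variable genes over a lineage's metacells
(minimal expression ``min_m le > -13``, dynamic range ``max - min le``
above a lineage-specific threshold, and a minimal gap between the endpoint
cell types' maxima), groups them into five k-means clusters on relative
expression ``lf``, and assembles endpoint gene programs from the extreme
clusters. Single-cell scores are UMI fractions over a program's genes; the
same formula serves the S-phase and M-phase cell-cycle scores. Pseudotime is
the arc-length position along a principal curve fitted to the joint 2-D score
distribution, divided into 12 equal-arc-length bins for expression kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

from .atlas import LE_PSEUDOCOUNT, MetacellModel
from .io import counts_matrix
from .markers import M_PHASE_GENES, S_PHASE_GENES  # noqa: F401  (re-exported)


@dataclass
class GeneProgram:
    name: str
    genes: list[str]
    provenance: list[int] = field(default_factory=list)  # source cluster ids

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene program {self.name!r} is empty")


@dataclass
class LineageGeneFilterParams:
    min_expr: float = -13.0  # on the le scale
    min_range: float = 2.0  # 2 for EPC/chorion, 4 for the PGC analysis
    min_endpoint_gap: float = 1.5  # 1.5 EPC, 1 chorion, 1.5 PGC
    n_clusters: int = 5

    def validate(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")


# ---------------------------------------------------------------------- #
# gene selection and programs
# ---------------------------------------------------------------------- #


def select_lineage_variable_genes(
    model: MetacellModel,
    lineage_types: list[str],
    endpoint_a: list[str],
    endpoint_b: list[str],
    params: LineageGeneFilterParams | None = None,
) -> pd.DataFrame:
    """Variable-gene screen over a lineage's metacells.

    Returns a table with the per-gene filter statistics, a ``selected`` flag
    and the ``side`` ("A"/"B") whose endpoint metacells carry the higher
    maximal expression.
    """
    params = params or LineageGeneFilterParams()
    params.validate()
    if set(endpoint_a) & set(endpoint_b):
        raise ValueError("endpoint cell types must not overlap")
    mcs = model.metacells_of_type(lineage_types)
    if len(mcs) < 3:
        raise ValueError("need at least 3 lineage metacells")
    a_mcs = model.metacells_of_type(endpoint_a)
    b_mcs = model.metacells_of_type(endpoint_b)
    le = model.le[mcs]
    stats = pd.DataFrame(
        {
            "min_le": le.min(axis=1),
            "max_le": le.max(axis=1),
            "max_a": model.le[a_mcs].max(axis=1),
            "max_b": model.le[b_mcs].max(axis=1),
        }
    )
    stats["range"] = stats.max_le - stats.min_le
    stats["endpoint_gap"] = (stats.max_a - stats.max_b).abs()
    stats["selected"] = (
        (stats.min_le > params.min_expr)
        & (stats.range > params.min_range)
        & (stats.endpoint_gap > params.min_endpoint_gap)
    )
    stats["side"] = np.where(stats.max_a >= stats.max_b, "A", "B")
    if not stats.selected.any():
        warnings.warn("no genes pass the lineage variable-gene filters")
    return stats


def cluster_lineage_genes(
    model: MetacellModel,
    genes: list[str],
    lineage_types: list[str],
    endpoint_a: list[str],
    endpoint_b: list[str],
    n_clusters: int = 5,
    program_names: tuple[str, str] = ("endpoint_a", "endpoint_b"),
    seed: int = 0,
) -> tuple[pd.Series, dict[str, GeneProgram]]:
    """k-means on relative expression, with canonical endpoint ordering.

    Cluster labels are re-ordered by mean A-endpoint minus B-endpoint
    relative expression (descending), so the mapping clusters 1-2 -> A-side
    program and clusters 4-5 -> B-side program is deterministic and invariant
    to gene input order.
    """
    if len(genes) < n_clusters:
        raise ValueError("fewer genes than clusters")
    mcs = model.metacells_of_type(lineage_types)
    genes = sorted(genes)  # input-order invariance
    lf = model.lf.loc[genes, mcs]
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(lf.to_numpy())
    raw = pd.Series(km.labels_, index=genes)
    a_mcs = [m for m in model.metacells_of_type(endpoint_a) if m in lf.columns]
    b_mcs = [m for m in model.metacells_of_type(endpoint_b) if m in lf.columns]
    polarity = {
        c: lf.loc[raw == c, a_mcs].to_numpy().mean() - lf.loc[raw == c, b_mcs].to_numpy().mean()
        for c in range(n_clusters)
    }
    order = sorted(polarity, key=lambda c: -polarity[c])
    relabel = {c: i + 1 for i, c in enumerate(order)}
    clusters = raw.map(relabel)

    half = n_clusters // 2
    a_ids = list(range(1, half + 1))  # e.g. clusters 1-2 of 5
    b_ids = list(range(n_clusters - half + 1, n_clusters + 1))  # e.g. 4-5
    prog_a = GeneProgram(program_names[0], sorted(clusters.index[clusters.isin(a_ids)]), a_ids)
    prog_b = GeneProgram(program_names[1], sorted(clusters.index[clusters.isin(b_ids)]), b_ids)
    return clusters, {program_names[0]: prog_a, program_names[1]: prog_b}


def cell_score(adata: ad.AnnData, program: GeneProgram) -> pd.Series:
    """UMI fraction over the program's genes, per cell; NaN for empty cells."""
    X = counts_matrix(adata)
    gi = adata.var_names.get_indexer([g for g in program.genes if g in adata.var_names])
    totals = np.asarray(X.sum(axis=1)).ravel()
    hits = np.asarray(X[:, gi].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
    if (totals == 0).any():
        warnings.warn(f"{int((totals == 0).sum())} zero-count cells scored as NaN")
    return pd.Series(score, index=adata.obs_names, name=program.name)


def cell_cycle_scores(adata: ad.AnnData) -> pd.DataFrame:
    """S-phase and M-phase scores (UMI fractions over the marker lists)."""
    s = cell_score(adata, GeneProgram("s_phase", list(S_PHASE_GENES)))
    m = cell_score(adata, GeneProgram("m_phase", list(M_PHASE_GENES)))
    return pd.DataFrame({"s_phase": s, "m_phase": m})


# ---------------------------------------------------------------------- #
# principal curve pseudotime
# ---------------------------------------------------------------------- #


@dataclass
class PseudotimeTrajectory:
    curve: np.ndarray  # ordered polyline vertices in score space
    cell_position: pd.Series  # arc-length position in [0, 1]
    n_iter: int
    converged: bool


def _project_to_polyline(P: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project points P (n,2) onto polyline V (m,2); return (arc_length, proj)."""
    seg = V[1:] - V[:-1]
    seg_len2 = np.maximum((seg**2).sum(axis=1), 1e-30)
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt(seg_len2))])
    # t[i, j]: position of point i along segment j
    diff = P[:, None, :] - V[None, :-1, :]
    t = np.clip((diff * seg[None]).sum(axis=2) / seg_len2[None], 0.0, 1.0)
    proj = V[None, :-1, :] + t[:, :, None] * seg[None]
    d2 = ((P[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(len(P))
    arc = cum[best] + t[rows, best] * np.sqrt(seg_len2[best])
    return arc, proj[rows, best]


def fit_principal_curve(
    scores: pd.DataFrame,
    anchor_a: pd.Series,
    span: float = 0.3,
    max_iter: int = 50,
    tol: float = 1e-4,
    max_vertices: int = 200,
    seed: int = 0,
) -> PseudotimeTrajectory:
    """Iterative projection-smoothing principal curve in 2-D score space.

    Initialized on the first principal component; each iteration smooths the
    coordinates against arc-length with lowess (local linear regression,
    fraction ``span``) and re-projects the cells onto the smoothed polyline.
    Converged when the mean projection displacement drops below ``tol``.
    Positions are normalized arc lengths in [0, 1], oriented so cells flagged
    in ``anchor_a`` sit near 0. Collinear input falls back to the PC1 line.
    """
    if scores.shape[1] != 2:
        raise ValueError("need exactly two score axes")
    if len(scores) < 50:
        raise ValueError("need at least 50 cells")
    P = scores.to_numpy(dtype=float)
    center = P.mean(axis=0)
    Pc = P - center
    _, s, Vt = np.linalg.svd(Pc, full_matrices=False)
    lam = Pc @ Vt[0]
    degenerate = s[1] < 1e-10 * max(s[0], 1e-30)
    if degenerate:
        warnings.warn("degenerate (collinear) input; using the PC1 line")
        order = np.argsort(lam)
        V = center + np.outer(np.linspace(lam.min(), lam.max(), 2), Vt[0])
        arc = lam - lam.min()
        return _finish(scores, anchor_a, V, arc, 0, True)

    prev_proj = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sx = lowess(P[:, 0], lam, frac=span, it=0, return_sorted=False)
        sy = lowess(P[:, 1], lam, frac=span, it=0, return_sorted=False)
        order = np.argsort(lam, kind="stable")
        V = np.column_stack([sx[order], sy[order]])
        # thin to distinct vertices, capped for projection cost
        keep = np.concatenate([[True], (np.abs(np.diff(V, axis=0)).sum(axis=1) > 1e-12)])
        V = V[keep]
        if len(V) < 2:
            warnings.warn("smoother collapsed the curve; using the PC1 line")
            V = center + np.outer(np.linspace(lam.min(), lam.max(), 2), Vt[0])
            arc, proj = _project_to_polyline(P, V)
            return _finish(scores, anchor_a, V, arc, it, True)
        if len(V) > max_vertices:
            take = np.unique(np.linspace(0, len(V) - 1, max_vertices).astype(int))
            V = V[take]
        arc, proj = _project_to_polyline(P, V)
        if prev_proj is not None:
            disp = float(np.mean(np.linalg.norm(proj - prev_proj, axis=1)))
            if disp < tol:
                converged = True
                break
        prev_proj = proj
        lam = arc
    return _finish(scores, anchor_a, V, arc, it, converged)


def _finish(
    scores: pd.DataFrame,
    anchor_a: pd.Series,
    V: np.ndarray,
    arc: np.ndarray,
    n_iter: int,
    converged: bool,
    trim_quantile: float = 0.01,
) -> PseudotimeTrajectory:
    # robust endpoint normalization: the position span covers the central
    # arc mass and outlying cells are clamped to the termini, so a few
    # stray cells cannot stretch the pseudotime axis
    lo = float(np.quantile(arc, trim_quantile))
    hi = float(np.quantile(arc, 1.0 - trim_quantile))
    rng = hi - lo
    if rng <= 0:
        lo, rng = arc.min(), max(arc.max() - arc.min(), 1.0)
    pos = np.clip((arc - lo) / rng, 0.0, 1.0)
    pos = pd.Series(pos, index=scores.index, name="position")
    mask = anchor_a.reindex(scores.index).fillna(False).astype(bool)
    if mask.any() and pos[mask].mean() > 0.5:
        pos = 1.0 - pos
        V = V[::-1].copy()
    return PseudotimeTrajectory(curve=V, cell_position=pos, n_iter=n_iter, converged=converged)


def pseudotime_kinetics(
    trajectory: PseudotimeTrajectory,
    adata: ad.AnnData,
    genes: list[str],
    n_bins: int = 12,
) -> dict:
    """Binned expression kinetics along the trajectory.

    Cells are assigned to ``n_bins`` equal-arc-length bins; per gene and bin
    the pooled absolute expression e (UMI fraction of the bin's pooled
    counts) and its log2(e + 1e-5) form are reported. Empty bins are flagged
    as missing (NaN), never interpolated. The midpoint bin is the one
    containing arc-length 0.5.
    """
    pos = trajectory.cell_position.reindex(adata.obs_names)
    bins = np.minimum((pos.to_numpy() * n_bins).astype(int), n_bins - 1) + 1
    X = counts_matrix(adata)
    gi = adata.var_names.get_indexer([g for g in genes if g in adata.var_names])
    present = [g for g in genes if g in adata.var_names]
    e = pd.DataFrame(np.nan, index=present, columns=range(1, n_bins + 1))
    counts_per_bin = pd.Series(0, index=range(1, n_bins + 1))
    for b in range(1, n_bins + 1):
        mask = bins == b
        counts_per_bin[b] = int(mask.sum())
        if mask.sum() == 0:
            continue
        pooled_tot = float(X[mask].sum())
        pooled = np.asarray(X[mask][:, gi].sum(axis=0)).ravel()
        e[b] = pooled / pooled_tot
    log_e = np.log2(e + LE_PSEUDOCOUNT)
    midpoint_bin = min(int(0.5 * n_bins), n_bins - 1) + 1
    return {
        "e": e,
        "log2_e": log_e,
        "bin_cells": counts_per_bin,
        "midpoint_bin": midpoint_bin,
        "n_bins": n_bins,
    }


def endpoint_fold(kinetics: dict, gene: str) -> float:
    """First-bin over last-bin pooled expression ratio for one gene."""
    e = kinetics["e"]
    first, last = e.columns[0], e.columns[-1]
    return float((e.loc[gene, first] + LE_PSEUDOCOUNT) / (e.loc[gene, last] + LE_PSEUDOCOUNT))


# ---------------------------------------------------------------------- #
# ExM PGC precursor identification
# ---------------------------------------------------------------------- #


def identify_exm_pgc_precursors(
    model: MetacellModel,
    pgc_score: pd.Series,  # per cell
    cell_Et: pd.Series,  # per cell
    pgc_types: list[str],
    band_quantiles: tuple[float, float] = (0.25, 0.75),
    et_max: float = 8.0,
    source: pd.Series | None = None,
) -> dict:
    """Flag metacells with intermediate PGC score and early developmental time.

    The intermediate band runs from the ``band_quantiles[1]`` quantile of
    non-PGC metacell mean scores up to the ``band_quantiles[0]`` quantile of
    PGC-annotated metacell mean scores; a flagged metacell must also have
    mean cell E_t below ``et_max``. Returns flagged metacells, their cells,
    and the per-source composition of flagged cells.
    """
    mc_score = pgc_score.groupby(model.partition).mean()
    mc_et = cell_Et.groupby(model.partition).mean()
    pgc_mcs = model.metacells_of_type(pgc_types)
    non_pgc = [m for m in model.metacells if m not in pgc_mcs]
    lo_q, hi_q = band_quantiles
    band_lo = float(mc_score[non_pgc].quantile(hi_q)) if non_pgc else 0.0
    band_hi = float(mc_score[pgc_mcs].quantile(lo_q)) if pgc_mcs else np.inf
    # candidates are non-PGC metacells: a precursor is by definition outside
    # the committed PGC pool; the lower band edge is inclusive
    flagged = [
        m
        for m in non_pgc
        if band_lo <= mc_score[m] < band_hi and mc_et[m] < et_max
    ]
    cells = model.partition.index[model.partition.isin(flagged)]
    composition = pd.Series(dtype=float)
    if source is not None and len(cells):
        composition = source.reindex(cells).value_counts(normalize=True)
    return {
        "metacells": flagged,
        "cells": list(cells),
        "composition": composition,
        "band": (band_lo, band_hi),
        "metacell_scores": mc_score,
        "metacell_Et": mc_et,
    }
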