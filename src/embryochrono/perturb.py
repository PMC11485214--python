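"""Projection of perturbed query cells onto a reference atlas, query-embryo
timing, and differential expression / composition statistics.

Annotation matches each query cell's atlas-neighbour cell-type distribution
to the best-correlated atlas cell's distribution; cells with too few atlas
neighbours fall back to a direct cell-metacell correlation
``cor_g(log2(u + 1), log2(e + 1e-5))``. Differential expression between two
pooled UMI groups uses a chi-square test on the 2x2 table
``(N1_g, N1 - N1_g)`` vs ``(N2_g, N2 - N2_g)`` without continuity correction,
Benjamini-Hochberg corrected. Expression fold-changes against projected
profiles use ``lfc = log2(mean e_query + eps) - log2(mean e_proj + eps)``
with ``eps = 5e-5``. Composition comparisons run per-embryo Wilcoxon
rank-sum tests (BH across cell types), pooled chi-square for low-frequency
types, or pooled log2 frequency ratios against a 2-fold reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .atlas import LE_PSEUDOCOUNT, MetacellModel
from .io import counts_matrix

LFC_EPSILON = 5e-5  # pseudo-expression guard in the lfc formula


@dataclass
class ProjectionResult:
    cell_annotation: pd.Series  # query cell -> atlas cell type ("" = unassigned)
    matched_atlas_cell: pd.Series  # query cell -> atlas cell name or ""
    fallback: pd.Series  # query cell -> bool (fallback annotation used)
    embryo_rank: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    query_metacell_projection: pd.DataFrame | None = None  # query mc -> atlas mc
    e_proj: pd.DataFrame | None = None  # genes x query metacells


def _feature_log(adata: ad.AnnData, features: list[str]) -> np.ndarray:
    X = counts_matrix(adata)
    fi = adata.var_names.get_indexer([g for g in features if g in adata.var_names])
    totals = np.maximum(np.asarray(X.sum(axis=1)).ravel(), 1)
    return np.log2(1.0 + np.asarray(X[:, fi].todense()) / totals[:, None] * 1e5)


def annotate_query_cells(
    query: ad.AnnData,
    atlas_counts: ad.AnnData,
    model: MetacellModel,
    atlas_celltype: pd.Series,
    features: list[str],
    K: int = 100,
    min_atlas_neighbours: int = 10,
) -> ProjectionResult:
    """Annotate query cells by matched atlas-neighbour type distributions.

    A joint query+atlas kNN graph is built on feature-gene log expression.
    For each cell (query and atlas alike) the empirical atlas-cell-type
    distribution among its K nearest atlas neighbours is computed; each query
    cell is matched to the best-correlated atlas cell among its neighbours
    and inherits that cell's type. Query cells with fewer than
    ``min_atlas_neighbours`` atlas cells among their K nearest joint
    neighbours are annotated by :func:`fallback_correlation_annotation`.
    """
    features = [g for g in features if g in query.var_names and g in atlas_counts.var_names]
    if not features:
        raise ValueError("no shared feature genes")
    qn, an = query.n_obs, atlas_counts.n_obs
    emb_q = _feature_log(query[:, features], features)
    emb_a = _feature_log(atlas_counts[:, features], features)
    joint = np.vstack([emb_a, emb_q])
    K_eff = min(K, an - 1)

    types = atlas_celltype.reindex(atlas_counts.obs_names)
    type_codes, type_index = pd.factorize(types, sort=True)
    n_types = len(type_index)

    # atlas-only neighbour graph: type distributions for atlas cells, and the
    # K atlas neighbours of every joint cell
    nn_atlas = NearestNeighbors(n_neighbors=K_eff + 1).fit(emb_a)
    _, a_idx = nn_atlas.kneighbors(joint)
    atlas_neigh = a_idx[:an, 1:]  # drop self for atlas cells
    query_neigh = a_idx[an:, :K_eff]

    def _distributions(neigh: np.ndarray) -> np.ndarray:
        d = np.zeros((len(neigh), n_types))
        codes = type_codes[neigh]
        for t in range(n_types):
            d[:, t] = (codes == t).mean(axis=1)
        return d

    dist_atlas = _distributions(atlas_neigh)
    dist_query = _distributions(query_neigh)

    # joint graph to count atlas neighbours among each query cell's K nearest
    nn_joint = NearestNeighbors(n_neighbors=min(K, an + qn - 1) + 1).fit(joint)
    _, j_idx = nn_joint.kneighbors(emb_q)
    j_idx = j_idx[:, 1:]  # queries are appended after the atlas; drop self
    n_atlas_neigh = (j_idx < an).sum(axis=1)

    annotation = pd.Series("", index=query.obs_names, dtype=object)
    matched = pd.Series("", index=query.obs_names, dtype=object)
    fallback = pd.Series(False, index=query.obs_names)
    atlas_names = np.asarray(atlas_counts.obs_names)

    centered_a = dist_atlas - dist_atlas.mean(axis=1, keepdims=True)
    norm_a = np.maximum(np.linalg.norm(centered_a, axis=1), 1e-12)
    for i in range(qn):
        if n_atlas_neigh[i] < min_atlas_neighbours:
            fallback.iloc[i] = True
            continue
        cand = query_neigh[i]
        dq = dist_query[i] - dist_query[i].mean()
        nq = np.linalg.norm(dq)
        if nq < 1e-12:
            corr = np.zeros(len(cand))
        else:
            corr = (centered_a[cand] @ dq) / (norm_a[cand] * nq)
        best = cand[int(np.argmax(corr))]
        matched.iloc[i] = atlas_names[best]
        annotation.iloc[i] = types.iloc[best]

    if fallback.any():
        fb_cells = list(fallback.index[fallback])
        fb_types = fallback_correlation_annotation(query[fb_cells], model, features)
        annotation[fb_cells] = fb_types
    return ProjectionResult(cell_annotation=annotation, matched_atlas_cell=matched, fallback=fallback)


def fallback_correlation_annotation(
    query: ad.AnnData, model: MetacellModel, features: list[str]
) -> pd.Series:
    """Best-correlated-metacell annotation over the feature genes.

    Pearson correlation between log2(count + 1) of the query cell and
    log2(e + 1e-5) of each atlas metacell, computed over exactly the feature
    list; ties break towards the lower metacell ID. Zero-variance query
    vectors are left unassigned ("").
    """
    features = [g for g in features if g in query.var_names and g in model.le.index]
    if not features:
        raise ValueError("empty feature list")
    X = counts_matrix(query)
    fi = query.var_names.get_indexer(features)
    U = np.log2(1.0 + np.asarray(X[:, fi].todense(), dtype=float))
    M = model.le.loc[features].to_numpy()  # features x metacells
    Uc = U - U.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=0, keepdims=True)
    un = np.linalg.norm(Uc, axis=1)
    mn = np.maximum(np.linalg.norm(Mc, axis=0), 1e-12)
    out = pd.Series("", index=query.obs_names, dtype=object)
    corr = (Uc @ Mc) / np.maximum(un[:, None], 1e-12) / mn[None, :]
    mcs = list(model.le.columns)
    for i in range(len(out)):
        if un[i] < 1e-12:
            continue
        best = mcs[int(np.argmax(corr[i]))]  # argmax returns first = lowest id on ties
        out.iloc[i] = model.celltype.get(best, "")
    return out


# ---------------------------------------------------------------------- #
# query embryo timing
# ---------------------------------------------------------------------- #


def time_query_embryos(
    query: ad.AnnData,
    atlas_counts: ad.AnnData,
    atlas_rank: pd.Series,  # atlas embryo -> rank
    features: list[str],
    min_cells: int = 5,
) -> pd.Series:
    """Match each query embryo to the WT rank with the most similar
    cumulative rank distribution.

    Each query cell inherits the rank of its nearest atlas neighbour's
    embryo; each atlas cell gets a resampled rank from its nearest neighbour
    belonging to a different atlas embryo. Query embryos with fewer than
    ``min_cells`` ranked cells are left unmatched (NaN).
    """
    features = [g for g in features if g in query.var_names and g in atlas_counts.var_names]
    emb_q = _feature_log(query[:, features], features)
    emb_a = _feature_log(atlas_counts[:, features], features)
    a_embryos = atlas_counts.obs["embryo"].to_numpy()
    ranks_of_embryo = atlas_rank.to_dict()

    nn = NearestNeighbors(n_neighbors=min(50, len(emb_a))).fit(emb_a)
    _, ai = nn.kneighbors(emb_a)
    a_cell_rank = np.full(len(emb_a), np.nan)
    for i in range(len(emb_a)):
        for j in ai[i]:
            if a_embryos[j] != a_embryos[i]:
                a_cell_rank[i] = ranks_of_embryo[a_embryos[j]]
                break

    # query cells inherit the *resampled* rank of their nearest atlas cell so
    # query and atlas embryo rank distributions are directly comparable (an
    # atlas embryo's own distribution is built from different-embryo
    # neighbours; inheriting raw embryo ranks would mix two distribution
    # families and break self-matching)
    _, qi = nn.kneighbors(emb_q)
    q_cell_rank = a_cell_rank[qi[:, 0]]
    missing = np.isnan(q_cell_rank)
    if missing.any():
        fallback = np.array(
            [ranks_of_embryo[a_embryos[j]] for j in qi[missing, 0]], dtype=float
        )
        q_cell_rank[missing] = fallback

    all_ranks = np.sort(atlas_rank.unique())

    def _cdf(vals: np.ndarray) -> np.ndarray:
        vals = vals[~np.isnan(vals)]
        return np.array([(vals <= r).mean() for r in all_ranks])

    wt_cdfs = {}
    for emb in atlas_rank.index:
        vals = a_cell_rank[a_embryos == emb]
        if len(vals):
            wt_cdfs[emb] = _cdf(vals)

    out = {}
    q_embryos = query.obs["embryo"]
    for emb in q_embryos.unique():
        vals = q_cell_rank[(q_embryos == emb).to_numpy()]
        if len(vals) < min_cells:
            out[emb] = np.nan
            continue
        qc = _cdf(vals)
        best, best_corr = None, -np.inf
        for wt, cdf in wt_cdfs.items():
            if np.std(cdf) < 1e-12 or np.std(qc) < 1e-12:
                corr = -np.inf
            else:
                corr = float(np.corrcoef(qc, cdf)[0, 1])
            if corr > best_corr:
                best, best_corr = wt, corr
        out[emb] = float(atlas_rank[best]) if best is not None else np.nan
    return pd.Series(out, name="matched_rank")


def match_batch_to_rank(
    batch_metacell_freq: pd.Series,  # atlas metacell -> frequency of batch cells
    per_embryo_freq: pd.DataFrame,  # embryos (rank order) x metacells
    atlas_rank: pd.Series,
    window: int = 20,
) -> str:
    """Batch-mode time matching: argmin over embryos of the L1 distance
    between the batch's metacell-frequency vector and the window-averaged
    per-embryo frequency vectors (window ``w`` in rank units)."""
    ranks = atlas_rank.reindex(per_embryo_freq.index)
    p_b = batch_metacell_freq.reindex(per_embryo_freq.columns).fillna(0.0).to_numpy()
    best, best_d = None, np.inf
    for emb in per_embryo_freq.index:
        in_win = ranks.index[(ranks - ranks[emb]).abs() <= window]
        p_bar = per_embryo_freq.loc[in_win].mean(axis=0).to_numpy()
        d = float(np.abs(p_b - p_bar).sum())
        if d < best_d:
            best, best_d = emb, d
    return best


# ---------------------------------------------------------------------- #
# metacell projection and fold changes
# ---------------------------------------------------------------------- #


def project_query_metacells(
    query_model: MetacellModel, atlas_model: MetacellModel, features: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match each query metacell with its best-correlated atlas metacell.

    Correlation form matches the fallback annotation
    (``cor(log2(u + 1), log2(e + 1e-5))`` over features, with query metacell
    pooled counts as u). Returns (assignment table, e_proj genes x query
    metacells) where each projected profile is the matched atlas metacell's
    ``e`` renormalized over the shared gene universe.
    """
    shared = [g for g in atlas_model.e.index if g in query_model.e.index]
    features = [g for g in features if g in shared]
    # u: query metacell pooled expression on the e scale; correlate log forms
    Uq = np.log2(1.0 + query_model.e.loc[features].to_numpy() * 1e4)  # scaled counts proxy
    Ea = np.log2(atlas_model.e.loc[features].to_numpy() + LE_PSEUDOCOUNT)
    Uc = Uq - Uq.mean(axis=0, keepdims=True)
    Ec = Ea - Ea.mean(axis=0, keepdims=True)
    corr = (Uc.T @ Ec) / np.maximum(
        np.linalg.norm(Uc, axis=0)[:, None] * np.linalg.norm(Ec, axis=0)[None, :], 1e-12
    )
    rows = []
    e_proj = {}
    atlas_mcs = list(atlas_model.e.columns)
    for j, qm in enumerate(query_model.e.columns):
        best = atlas_mcs[int(np.argmax(corr[j]))]
        rows.append(
            {
                "query_metacell": qm,
                "atlas_metacell": best,
                "correlation": float(corr[j].max()),
                "atlas_celltype": atlas_model.celltype.get(best, ""),
            }
        )
        prof = atlas_model.e.loc[shared, best]
        e_proj[qm] = prof / prof.sum()
    return pd.DataFrame(rows).set_index("query_metacell"), pd.DataFrame(e_proj, index=shared)


# ---------------------------------------------------------------------- #
# differential expression statistics
# ---------------------------------------------------------------------- #


def chisq_de(group1: np.ndarray | pd.Series, group2: np.ndarray | pd.Series) -> pd.DataFrame:
    """Per-gene chi-square DE on pooled UMI counts.

    For each gene g the 2x2 table (N1_g, N1 - N1_g) vs (N2_g, N2 - N2_g) is
    tested with the df=1 chi-square statistic, no continuity correction;
    p-values are BH-corrected across the tested genes. Genes with zero counts
    in both groups are excluded (p undefined).
    """
    g1 = pd.Series(group1).astype(float)
    g2 = pd.Series(group2).astype(float)
    if not g1.index.equals(g2.index):
        g2 = g2.reindex(g1.index)
    N1, N2 = float(g1.sum()), float(g2.sum())
    if N1 <= 0 or N2 <= 0:
        raise ValueError("both groups must contain counts")
    a, c = g1.to_numpy(), g2.to_numpy()
    b, d = N1 - a, N2 - c
    tested = (a + c) > 0
    n = N1 + N2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    stat = np.where(tested, stat, np.nan)
    p = np.where(tested, stats.chi2.sf(stat, df=1), np.nan)
    out = pd.DataFrame({"N1_g": a, "N2_g": c, "statistic": stat, "p": p}, index=g1.index)
    out["q"] = np.nan
    out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def lfc_vs_projection(
    cell_groups: pd.DataFrame,  # columns: cell, celltype, condition, metacell
    e_query: pd.DataFrame,  # genes x query metacells
    e_proj: pd.DataFrame,  # genes x query metacells
    epsilon: float = LFC_EPSILON,
) -> tuple[pd.DataFrame, pd.Series]:
    """Fold changes of pseudo-bulk query vs projected expression.

    For each cell type t and condition b:
    ``lfc[g] = log2(mean_c e_query[g, m(c)] + eps) - log2(mean_c e_proj[g, m(c)] + eps)``
    averaging over the cells c in (b, t) through their metacell m(c).
    Returns (lfc table genes x "condition|celltype" columns, cell counts
    N_{b,t}); combinations with no cells are omitted.
    """
    genes = e_query.index
    cols, ncells = {}, {}
    for (b, t), grp in cell_groups.groupby(["condition", "celltype"], observed=True):
        if len(grp) == 0:
            continue
        mcs = grp["metacell"].to_numpy()
        mq = e_query[mcs].mean(axis=1)
        mp = e_proj[mcs].mean(axis=1)
        key = f"{b}|{t}"
        cols[key] = np.log2(mq + epsilon) - np.log2(mp + epsilon)
        ncells[key] = len(grp)
    lfc = pd.DataFrame(cols, index=genes)
    return lfc, pd.Series(ncells, name="N_bt")


def screen_lateral_genes(
    lfc: pd.DataFrame,  # genes x "condition|celltype"
    control_conditions: list[str],
    expr_pass: pd.Series | None = None,
    lfc_threshold: float = 0.8,
    control_lfc_threshold: float = 0.4,
    n_clusters: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag lateral (batch/nuisance) genes among differential candidates.

    Candidates have max |lfc| > ``lfc_threshold`` over all (cell type,
    condition) columns (and pass the optional minimal-expression flag);
    candidates are k-means clustered on their lfc profiles and clusters whose
    mean |lfc| in any control condition exceeds ``control_lfc_threshold`` are
    classified lateral.
    """
    maxabs = lfc.abs().max(axis=1)
    cand = maxabs > lfc_threshold
    if expr_pass is not None:
        cand &= expr_pass.reindex(lfc.index).fillna(False).astype(bool)
    out = pd.DataFrame({"max_abs_lfc": maxabs, "candidate": cand})
    out["cluster"] = -1
    out["lateral"] = False
    cand_genes = list(lfc.index[cand])
    if not cand_genes:
        return out
    k = n_clusters
    if len(cand_genes) < k:
        warnings.warn(f"only {len(cand_genes)} DE candidates; reducing cluster count")
        k = max(1, len(cand_genes) // 2)
    prof = lfc.loc[cand_genes].fillna(0.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(prof.to_numpy())
    out.loc[cand_genes, "cluster"] = km.labels_
    ctrl_cols = [c for c in lfc.columns if c.split("|")[0] in control_conditions]
    if not ctrl_cols:
        raise ValueError("no control-condition columns in the lfc table")
    for c in range(k):
        genes_c = [g for g, lab in zip(cand_genes, km.labels_) if lab == c]
        ctrl_mean = prof.loc[genes_c, ctrl_cols].abs().mean().max()
        if ctrl_mean > control_lfc_threshold:
            out.loc[genes_c, "lateral"] = True
    return out


def per_embryo_celltype_de(
    f_query: dict[tuple[str, str], pd.Series],  # (embryo, celltype) -> gene freq
    f_wt: dict[tuple[str, str], pd.Series],  # matched WT pool freq, same keys
    cells_per_group: pd.Series | None = None,
    lateral_genes: set[str] | None = None,
    fold_threshold: float = 3.0,
    min_expr: float = 1e-4,
    min_cells: int = 10,
    n_clusters: int = 3,
    epsilon: float = LFC_EPSILON,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-embryo, per-cell-type DE against time-matched WT pools.

    A gene qualifies when, in at least one (embryo, cell type) with at least
    ``min_cells`` query cells, |log2(f_q + eps) - log2(f_wt + eps)| >=
    log2(``fold_threshold``) and max(f_q, f_wt) >= ``min_expr``. Lateral
    genes are removed; survivors are clustered into ``n_clusters`` k-means
    groups on their fold-change profiles.
    """
    lateral_genes = lateral_genes or set()
    keys = [
        k
        for k in f_query
        if k in f_wt and (cells_per_group is None or cells_per_group.get(k, 0) >= min_cells)
    ]
    if not keys:
        return pd.DataFrame(columns=["max_abs_lfc", "max_expr", "selected", "cluster"])
    genes = f_query[keys[0]].index
    lfc_cols = {}
    expr_cols = {}
    for k in keys:
        fq = f_query[k].reindex(genes).fillna(0.0)
        fw = f_wt[k].reindex(genes).fillna(0.0)
        lfc_cols[k] = np.log2(fq + epsilon) - np.log2(fw + epsilon)
        expr_cols[k] = np.maximum(fq, fw)
    lfc = pd.DataFrame(lfc_cols)
    expr = pd.DataFrame(expr_cols)
    out = pd.DataFrame(
        {"max_abs_lfc": lfc.abs().max(axis=1), "max_expr": expr.max(axis=1)}, index=genes
    )
    out["selected"] = (
        (out.max_abs_lfc >= np.log2(fold_threshold))
        & (out.max_expr >= min_expr)
        & (~out.index.isin(lateral_genes))
    )
    out["cluster"] = -1
    sel = list(out.index[out.selected])
    if len(sel) >= n_clusters:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(
            lfc.loc[sel].to_numpy()
        )
        out.loc[sel, "cluster"] = km.labels_ + 1
    elif sel:
        out.loc[sel, "cluster"] = 1
    return out


# ---------------------------------------------------------------------- #
# composition statistics
# ---------------------------------------------------------------------- #


def compare_celltype_frequencies(
    comp1: pd.DataFrame,  # embryos x cell types, rows sum to 1
    comp2: pd.DataFrame,
    mode: str = "per_embryo",
    cells1: pd.Series | None = None,  # pooled cell counts per type (pooled modes)
    cells2: pd.Series | None = None,
    min_embryos: int = 3,
    epsilon: float = LFC_EPSILON,
) -> pd.DataFrame:
    """Cell-type composition comparison between two embryo groups.

    mode "per_embryo": two-sided Wilcoxon rank-sum on per-embryo frequencies
    per cell type, BH across types (types are skipped when either group has
    fewer than ``min_embryos`` embryos). mode "pooled_lowfreq": two-tailed
    chi-square on pooled counts (type vs rest, group vs group). mode
    "pooled_ratio": pooled group-1:group-2 frequency ratio on the log2 scale
    with the 2-fold reference threshold.
    """
    if mode == "per_embryo":
        for comp in (comp1, comp2):
            sums = comp.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("per-embryo compositions must sum to 1")
        types = sorted(set(comp1.columns) | set(comp2.columns))
        rows = []
        for t in types:
            x = comp1.get(t, pd.Series(0.0, index=comp1.index)).to_numpy()
            y = comp2.get(t, pd.Series(0.0, index=comp2.index)).to_numpy()
            if len(x) < min_embryos or len(y) < min_embryos:
                warnings.warn(f"cell type {t!r} skipped: fewer than {min_embryos} embryos")
                continue
            if np.array_equal(np.sort(x), np.sort(y)):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ranksums(x, y)
            rows.append(
                {
                    "celltype": t,
                    "median1": float(np.median(x)),
                    "median2": float(np.median(y)),
                    "statistic": stat,
                    "p": p,
                }
            )
        out = pd.DataFrame(rows).set_index("celltype")
        out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
        return out

    if cells1 is None or cells2 is None:
        raise ValueError("pooled modes require per-type pooled cell counts")
    types = sorted(set(cells1.index) | set(cells2.index))
    n1, n2 = float(cells1.sum()), float(cells2.sum())
    if mode == "pooled_lowfreq":
        rows = []
        for t in types:
            a = float(cells1.get(t, 0))
            c = float(cells2.get(t, 0))
            table = np.array([[a, n1 - a], [c, n2 - c]])
            if table[:, 0].sum() == 0:
                continue
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append({"celltype": t, "count1": a, "count2": c, "statistic": stat, "p": p})
        out = pd.DataFrame(rows).set_index("celltype")
        out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
        return out

    if mode == "pooled_ratio":
        rows = []
        for t in types:
            f1 = float(cells1.get(t, 0)) / n1
            f2 = float(cells2.get(t, 0)) / n2
            rows.append(
                {
                    "celltype": t,
                    "freq1": f1,
                    "freq2": f2,
                    "log2_ratio": float(np.log2(f1 + epsilon) - np.log2(f2 + epsilon)),
                }
            )
        out = pd.DataFrame(rows).set_index("celltype")
        out["beyond_2fold"] = out.log2_ratio.abs() > 1.0
        return out

    raise ValueError(f"unknown mode {mode!r}")


def exe_embryonic_ratio(
    cell_meta: pd.DataFrame,  # columns: embryo, celltype
    age_bin: pd.Series,  # embryo -> bin
    exe_types: list[str],
) -> pd.Series:
    """ExE-to-embryonic cell-count ratio per age bin."""
    df = cell_meta.copy()
    df["bin"] = age_bin.reindex(df["embryo"]).to_numpy()
    df["is_exe"] = df["celltype"].isin(exe_types)
    grp = df.groupby("bin")["is_exe"].agg(["sum", "count"])
    emb = grp["count"] - grp["sum"]
    return (grp["sum"] / emb.replace(0, np.nan)).rename("exe_embryonic_ratio")
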