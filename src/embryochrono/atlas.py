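"""Feature-gene selection and metacell expression modelling.

A metacell is a small group of transcriptionally homogeneous cells pooled to
de-sparsify UMI counts. For a metacell m the absolute expression of gene g is

    e[g, m] = sum_{c in m} N[g, c] / sum_g sum_{c in m} N[g, c]

with log form ``le = log2(e + 1e-5)`` and relative expression
``lf = le - mean_m(le)``. Feature genes are selected by a variance/mean
threshold on depth-downsampled counts (T_vm), total-coverage thresholds
(T_tot, T_top3), and removal of gene clusters enriched for cell-cycle or
stress programs. The cell partition itself uses a cosine-similarity balanced
kNN graph with seeded Leiden modularity clustering and a minimum-size merge;
the published metacell packages' internal partition heuristics are not
reproduced, only their stated constraints (Knn, minimal size) are honoured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import counts_matrix

LE_PSEUDOCOUNT = 1e-5  # fixed by the expression model; not configurable


@dataclass
class FeatureSelectionParams:
    T_vm: float = 0.1
    T_tot: float = 50.0
    T_top3: float = 3.0
    n_gene_clusters: int = 120

    def validate(self) -> None:
        if min(self.T_vm, self.T_tot, self.T_top3) < 0:
            raise ValueError("feature-selection thresholds must be >= 0")


@dataclass
class MetacellModel:
    partition: pd.Series  # cell -> metacell id (int)
    e: pd.DataFrame  # genes x metacells
    le: pd.DataFrame
    lf: pd.DataFrame
    celltype: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    Knn: int = 100
    min_size: int = 20

    @property
    def metacells(self) -> list[int]:
        return list(self.e.columns)

    def sizes(self) -> pd.Series:
        return self.partition.value_counts().sort_index()

    def annotate(self, cell_labels: pd.Series) -> None:
        """Set each metacell's type to the majority label among its cells."""
        df = pd.DataFrame({"mc": self.partition, "lab": cell_labels.reindex(self.partition.index)})
        self.celltype = df.groupby("mc")["lab"].agg(lambda s: s.value_counts().index[0])

    def metacells_of_type(self, types: str | list[str]) -> list[int]:
        if isinstance(types, str):
            types = [types]
        return [m for m in self.metacells if self.celltype.get(m) in types]


# ---------------------------------------------------------------------- #
# feature selection
# ---------------------------------------------------------------------- #


def downsample_counts(X: sp.csr_matrix, target: int, seed: int = 0) -> sp.csr_matrix:
    """Downsample each cell with more than ``target`` UMIs to ``target``.

    Multinomial resampling at the cell's empirical gene frequencies; cells at
    or below the target are kept as-is. Removes the depth-driven component of
    per-gene variance before variance/mean screening.
    """
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    rows = []
    for i in range(X.shape[0]):
        row = X[i]
        if totals[i] <= target:
            rows.append(row)
            continue
        p = row.toarray().ravel() / totals[i]
        rows.append(sp.csr_matrix(rng.multinomial(target, p)))
    return sp.vstack(rows, format="csr")


def select_feature_genes(
    adata: ad.AnnData,
    params: FeatureSelectionParams | None = None,
    lateral_markers: dict[str, list[str]] | None = None,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Select variable, covered genes and drop lateral gene clusters.

    Keeps genes whose downsampled variance/mean >= T_vm, raw total UMIs >=
    T_tot and third-largest per-cell count >= T_top3; clusters the candidates
    on gene-gene correlation of log expression (seeded k-means) and removes
    clusters enriched for any supplied lateral marker set (cell cycle,
    stress). Returns the feature list and a per-gene diagnostic table.
    """
    params = params or FeatureSelectionParams()
    params.validate()
    X = counts_matrix(adata)
    totals = np.asarray(X.sum(axis=1)).ravel()
    target = int(np.median(totals))
    Xd = downsample_counts(X, target, seed=seed)

    dsd = np.asarray(Xd.todense(), dtype=float)
    mean = dsd.mean(axis=0)
    var = dsd.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vm = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    tot = np.asarray(X.sum(axis=0)).ravel()
    dense = np.asarray(X.todense())
    top3 = np.partition(dense, -3, axis=0)[-3] if dense.shape[0] >= 3 else dense.min(axis=0)

    stats = pd.DataFrame(
        {"var_over_mean": vm, "total": tot, "top3": top3}, index=adata.var_names
    )
    cand = stats.index[
        (stats.var_over_mean >= params.T_vm)
        & (stats.total >= params.T_tot)
        & (stats.top3 >= params.T_top3)
    ].tolist()
    stats["candidate"] = stats.index.isin(cand)
    stats["feature"] = False
    if not cand:
        return [], stats

    k = params.n_gene_clusters
    if len(cand) < k:
        warnings.warn(f"only {len(cand)} candidates; lowering gene cluster count")
        k = max(2, len(cand) // 2)
    logx = np.log2(1.0 + dense[:, adata.var_names.get_indexer(cand)].astype(float))
    km = KMeans(n_clusters=k, n_init=5, random_state=seed).fit(logx.T)
    clusters = pd.Series(km.labels_, index=cand)

    flagged: set[int] = set()
    if lateral_markers:
        flagged = flag_lateral_gene_clusters(clusters, lateral_markers, universe=len(adata.var_names))
    features = [g for g in cand if clusters[g] not in flagged]
    stats.loc[features, "feature"] = True
    stats["gene_cluster"] = clusters.reindex(stats.index)
    return features, stats


def flag_lateral_gene_clusters(
    gene_clusters: pd.Series,
    marker_sets: dict[str, list[str]],
    universe: int | None = None,
    q_threshold: float = 0.05,
    min_overlap: int = 3,
) -> set[int]:
    """Flag gene clusters enriched for any lateral marker set.

    Hypergeometric enrichment of each (cluster, marker set) pair over the
    gene universe, Benjamini-Hochberg across pairs; a cluster is flagged when
    any set reaches q < ``q_threshold`` with overlap >= ``min_overlap``. This
    replaces manual curation of cell-cycle/stress clusters with a fixed rule.
    """
    N = universe if universe is not None else len(gene_clusters)
    tests = []
    for cid, members in gene_clusters.groupby(gene_clusters).groups.items():
        cluster_genes = set(members)
        for mname, markers in marker_sets.items():
            mset = set(markers)
            ov = len(cluster_genes & mset)
            p = hypergeom.sf(ov - 1, N, len(mset), len(cluster_genes))
            tests.append((cid, mname, ov, p))
    if not tests:
        return set()
    df = pd.DataFrame(tests, columns=["cluster", "marker_set", "overlap", "p"])
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    hit = df[(df["q"] < q_threshold) & (df["overlap"] >= min_overlap)]
    return set(hit["cluster"])


# ---------------------------------------------------------------------- #
# metacell construction
# ---------------------------------------------------------------------- #


def build_metacells(
    adata: ad.AnnData,
    features: list[str],
    Knn: int = 100,
    min_size: int = 20,
    target_size: int = 60,
    seed: int = 0,
) -> MetacellModel:
    """Partition cells into metacells and compute the expression model.

    Cells are embedded in log feature-gene expression; a cosine-similarity
    balanced kNN graph is clustered with seeded Leiden modularity (the
    resolution is bisected so community count tracks ``n_cells/target_size``),
    and groups below ``min_size`` are merged into their most similar
    neighbouring group.
    """
    n = adata.n_obs
    if n < min_size:
        warnings.warn("fewer cells than min_size; returning a single metacell")
        labels = np.zeros(n, dtype=int)
    else:
        X = counts_matrix(adata)
        fi = adata.var_names.get_indexer([g for g in features if g in adata.var_names])
        if len(fi) == 0:
            raise ValueError("no feature genes present in the matrix")
        totals = np.maximum(np.asarray(X.sum(axis=1)).ravel(), 1)
        emb = np.log2(1.0 + np.asarray(X[:, fi].todense()) / totals[:, None] * 1e5)
        norms = np.linalg.norm(emb, axis=1)
        emb = emb / np.maximum(norms, 1e-12)[:, None]

        k = min(Knn, n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(emb)
        dist, idx = nn.kneighbors(emb)
        src = np.repeat(np.arange(n), k)
        dst = idx[:, 1:].ravel()
        wts = 1.0 - dist[:, 1:].ravel()  # cosine similarity
        edges = {}
        for s, d, w in zip(src, dst, wts):
            key = (min(s, d), max(s, d))
            edges[key] = max(edges.get(key, 0.0), max(w, 1e-6))
        g = igraph.Graph(n=n, edges=list(edges.keys()))
        g.es["weight"] = list(edges.values())

        n_target = max(1, n // target_size)
        labels = _leiden_with_target(g, n_target, seed)
        labels = _split_large(labels, emb, target_size, seed)
        labels = _merge_small(labels, emb, min_size)

    labels = pd.Series(labels, index=adata.obs_names, name="metacell")
    e, le, lf = metacell_expression(labels, adata)
    return MetacellModel(partition=labels, e=e, le=le, lf=lf, Knn=Knn, min_size=min_size)


def _leiden_with_target(g: igraph.Graph, n_target: int, seed: int) -> np.ndarray:
    """Bisect the Leiden resolution towards roughly ``n_target`` communities."""
    lo, hi = 1e-4, 50.0
    best = None
    for _ in range(12):
        res = float(np.sqrt(lo * hi))
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=res,
            seed=seed,
            n_iterations=2,
        )
        k = len(part)
        if best is None or abs(k - n_target) < abs(best[0] - n_target):
            best = (k, np.array(part.membership))
        if k < n_target:
            lo = res
        elif k > n_target:
            hi = res
        else:
            break
    return best[1]


def _split_large(
    labels: np.ndarray, emb: np.ndarray, target_size: int, seed: int
) -> np.ndarray:
    """Split communities above 2x the target size by within-community k-means,
    keeping metacells near the conventional 20-100 cell scale."""
    labels = labels.copy()
    next_id = labels.max() + 1
    for i in np.unique(labels):
        members = np.where(labels == i)[0]
        if len(members) <= 2 * target_size:
            continue
        k = int(np.ceil(len(members) / target_size))
        sub = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(emb[members])
        for j in range(1, k):
            labels[members[sub == j]] = next_id
            next_id += 1
    return labels


def _merge_small(labels: np.ndarray, emb: np.ndarray, min_size: int) -> np.ndarray:
    """Merge groups below min_size into the nearest group by centroid cosine."""
    labels = labels.copy()
    while True:
        ids, sizes = np.unique(labels, return_counts=True)
        small = ids[sizes < min_size]
        if len(small) == 0 or len(ids) == 1:
            break
        centroids = np.vstack([emb[labels == i].mean(axis=0) for i in ids])
        centroids /= np.maximum(np.linalg.norm(centroids, axis=1), 1e-12)[:, None]
        s = small[np.argmin(sizes[np.isin(ids, small)])]
        si = np.where(ids == s)[0][0]
        sims = centroids @ centroids[si]
        sims[si] = -np.inf
        target = ids[int(np.argmax(sims))]
        labels[labels == s] = target
    # relabel contiguously, ordered by first occurrence for determinism
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def metacell_expression(
    partition: pd.Series, adata: ad.AnnData
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pool counts per metacell and return (e, le, lf), genes x metacells."""
    if not partition.index.equals(adata.obs_names) and set(partition.index) != set(
        adata.obs_names
    ):
        raise ValueError("partition must cover all cells")
    X = counts_matrix(adata)
    part = partition.reindex(adata.obs_names)
    ids = sorted(part.unique())
    pooled = np.zeros((adata.n_vars, len(ids)))
    for j, m in enumerate(ids):
        mask = (part == m).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"empty metacell {m}")
        pooled[:, j] = np.asarray(X[mask].sum(axis=0)).ravel()
    tot = pooled.sum(axis=0)
    if (tot == 0).any():
        raise ValueError("metacell with zero total counts")
    e = pd.DataFrame(pooled / tot, index=adata.var_names, columns=ids)
    le = np.log2(e + LE_PSEUDOCOUNT)
    lf = le.sub(le.mean(axis=1), axis=0)
    return e, le, lf
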