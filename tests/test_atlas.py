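"""Feature selection, lateral-cluster flagging and the metacell model."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from embryochrono import atlas, syndata
from embryochrono.atlas import LE_PSEUDOCOUNT


def _toy_adata(X, genes=None, cells=None):
    X = np.asarray(X, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    cells = cells or [f"c{i}" for i in range(X.shape[0])]
    return ad.AnnData(
        X=X, obs=pd.DataFrame(index=cells), var=pd.DataFrame(index=genes)
    )


class TestFeatureSelection:
    def test_coverage_and_variance_thresholds(self):
        rng = np.random.default_rng(0)
        n = 60
        flat = np.full((n, 1), 10)  # zero variance at equal depth
        rare = np.zeros((n, 1), dtype=int)
        rare[0] = 2  # total 2 < T_tot
        good = np.where(rng.random(n) < 0.5, 2, 38)[:, None]
        # balance totals so depth-downsampling is a no-op and the
        # zero-variance gene stays exactly constant
        filler = 60 - flat - rare - good
        adata = _toy_adata(
            np.hstack([flat, rare, good, filler]),
            genes=["flat", "rare", "good", "filler"],
        )
        feats, stats = atlas.select_feature_genes(adata, seed=0)
        assert not stats.loc["flat", "candidate"]  # var/mean ~ 0 < 0.1
        assert not stats.loc["rare", "candidate"]  # total 2 < 50
        assert stats.loc["good", "candidate"]

    def test_planted_variable_genes_recovered(self):
        """>= 18 of 20 planted bimodal genes survive the screen among flats."""
        rng = np.random.default_rng(1)
        n = 300
        group = rng.random(n) < 0.5
        planted = np.vstack(
            [rng.poisson(np.where(group, 1.0, 25.0)) for _ in range(20)]
        ).T
        flats = rng.poisson(5.0, size=(n, 480))
        genes = [f"planted{i}" for i in range(20)] + [f"flat{i}" for i in range(480)]
        adata = _toy_adata(np.hstack([planted, flats]), genes=genes)
        feats, _ = atlas.select_feature_genes(adata, seed=1)
        hits = sum(1 for g in feats if g.startswith("planted"))
        assert hits >= 18


class TestLateralFlagging:
    def test_complete_overlap_flagged(self):
        markers = {"m": [f"x{i}" for i in range(10)]}
        clusters = pd.Series(
            [0] * 10 + [1] * 10,
            index=markers["m"] + [f"other{i}" for i in range(10)],
        )
        flagged = atlas.flag_lateral_gene_clusters(clusters, markers, universe=500)
        assert flagged == {0}

    def test_zero_overlap_not_flagged(self):
        clusters = pd.Series([0] * 10, index=[f"other{i}" for i in range(10)])
        flagged = atlas.flag_lateral_gene_clusters(clusters, {"m": ["x1", "x2", "x3"]})
        assert flagged == set()

    def test_planted_enrichment_hypergeometric(self):
        """A 10/20 cell-cycle cluster among many flat clusters is flagged;
        the decision agrees with a direct hypergeometric computation."""
        rng = np.random.default_rng(2)
        cc = [f"cc{i}" for i in range(30)]
        labels, index = [], []
        index += [f"cc{i}" for i in range(10)] + [f"bg{i}" for i in range(10)]
        labels += [0] * 20
        for c in range(1, 40):
            index += [f"flat{c}_{i}" for i in range(12)]
            labels += [c] * 12
        clusters = pd.Series(labels, index=index)
        N = len(clusters)
        flagged = atlas.flag_lateral_gene_clusters(clusters, {"cc": cc}, universe=N)
        p_direct = hypergeom.sf(10 - 1, N, 30, 20)
        assert p_direct < 1e-6  # overwhelming enrichment survives BH trivially
        assert 0 in flagged
        assert all(c not in flagged for c in range(1, 40))


class TestMetacellExpression:
    def test_single_cell_normalization(self):
        adata = _toy_adata([[2, 2]], genes=["gA", "gB"])
        part = pd.Series([0], index=adata.obs_names)
        e, le, lf = atlas.metacell_expression(part, adata)
        assert e.loc["gA", 0] == pytest.approx(0.5)
        assert e.loc["gB", 0] == pytest.approx(0.5)

    def test_two_cell_pooling(self):
        adata = _toy_adata([[1, 0], [1, 2]], genes=["gA", "gB"])
        part = pd.Series([0, 0], index=adata.obs_names)
        e, _, _ = atlas.metacell_expression(part, adata)
        assert e.loc["gA", 0] == pytest.approx(0.5)
        assert e.loc["gB", 0] == pytest.approx(0.5)

    def test_normalization_identity_and_pseudocount(self, small_model):
        model, _ = small_model
        sums = model.e.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)
        zero_mask = model.e == 0
        if zero_mask.any().any():
            assert np.allclose(
                model.le.values[zero_mask.values], np.log2(LE_PSEUDOCOUNT)
            )
        assert np.allclose(model.lf.mean(axis=1), 0.0, atol=1e-9)

    def test_dominant_gene(self):
        adata = _toy_adata([[7, 0]], genes=["g", "absent"])
        part = pd.Series([0], index=adata.obs_names)
        e, le, _ = atlas.metacell_expression(part, adata)
        assert e.loc["g", 0] == pytest.approx(1.0)
        assert le.loc["absent", 0] == pytest.approx(np.log2(1e-5))

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(3.0, size=(30, 8))
        adata = _toy_adata(X)
        part = pd.Series(rng.integers(0, 3, 30), index=adata.obs_names)
        e1, _, _ = atlas.metacell_expression(part, adata)
        perm = rng.permutation(30)
        e2, _, _ = atlas.metacell_expression(part.iloc[perm], adata[perm])
        pd.testing.assert_frame_equal(e1, e2)

    def test_empty_metacell_raises(self):
        adata = _toy_adata([[1, 1]])
        part = pd.Series([0], index=["missing_cell"])
        with pytest.raises(ValueError):
            atlas.metacell_expression(part, adata)


def _four_state_cohort(seed=17):
    """Four well-separated states with distinct marker blocks."""
    rng = np.random.default_rng(seed)
    n_genes = 200
    base = np.exp(rng.normal(0, 1, n_genes)) * 1e-3
    states = []
    for k in range(4):
        vec = base.copy()
        vec[k * 20 : (k + 1) * 20] *= 10.0
        states.append(syndata.StateSpec(f"s{k}", expression=vec))
    spec = syndata.CohortSpec(
        n_embryos=4,
        cells_per_embryo=(150, 150),
        n_genes=n_genes,
        states=states,
        state_frequency_curves={f"s{k}": (lambda t: 0.25) for k in range(4)},
        umi_depth=2000,
        seed=seed,
    )
    return syndata.generate_atlas_cohort(spec)


class TestBuildMetacells:
    def test_purity_and_min_size(self):
        """On a 4-state cohort nearly every metacell is state-pure."""
        cohort = _four_state_cohort()
        feats, _ = atlas.select_feature_genes(cohort.counts, seed=17)
        model = atlas.build_metacells(cohort.counts, feats, seed=17)
        sizes = model.sizes()
        assert (sizes >= model.min_size).all()
        truth = cohort.counts.obs["true_state"]
        purities = []
        for m in model.metacells:
            cells = model.partition.index[model.partition == m]
            purities.append(truth.loc[cells].value_counts(normalize=True).iloc[0])
        frac_pure = np.mean([p >= 0.8 for p in purities])
        assert frac_pure >= 0.95

    def test_seed_reproducibility(self, small_cohort):
        feats, _ = atlas.select_feature_genes(small_cohort.counts, seed=9)
        m1 = atlas.build_metacells(small_cohort.counts, feats, seed=9)
        m2 = atlas.build_metacells(small_cohort.counts, feats, seed=9)
        pd.testing.assert_series_equal(m1.partition, m2.partition)

    def test_single_metacell_fallback(self):
        adata = _toy_adata(np.random.default_rng(0).poisson(5, size=(5, 6)))
        with pytest.warns(UserWarning):
            model = atlas.build_metacells(adata, list(adata.var_names), min_size=20)
        assert len(model.metacells) == 1
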