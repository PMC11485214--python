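"""Gene programs, single-cell scores, principal-curve pseudotime, kinetics."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, spearmanr
from sklearn.metrics import adjusted_rand_score

from embryochrono import kinetics
from embryochrono.atlas import MetacellModel
from embryochrono.kinetics import (
    GeneProgram,
    M_PHASE_GENES,
    S_PHASE_GENES,
    LineageGeneFilterParams,
)


def _model_from_e(e: pd.DataFrame, celltype: dict) -> MetacellModel:
    le = np.log2(e + 1e-5)
    lf = le.sub(le.mean(axis=1), axis=0)
    part = pd.Series({f"cell{m}": m for m in e.columns})
    return MetacellModel(
        partition=part, e=e, le=le, lf=lf, celltype=pd.Series(celltype)
    )


class TestMarkerLists:
    def test_cell_cycle_list_sizes(self):
        assert len(M_PHASE_GENES) == 26
        assert len(S_PHASE_GENES) == 11
        assert len(set(M_PHASE_GENES) | set(S_PHASE_GENES)) == 37


class TestCellScore:
    def _adata(self, X, genes):
        return ad.AnnData(
            X=np.asarray(X, dtype=np.int64),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(len(X))]),
            var=pd.DataFrame(index=genes),
        )

    def test_hand_arithmetic_and_limits(self):
        adata = self._adata([[3, 1]], ["a", "b"])
        assert kinetics.cell_score(adata, GeneProgram("p", ["a"]))["c0"] == pytest.approx(0.75)
        assert kinetics.cell_score(adata, GeneProgram("all", ["a", "b"]))["c0"] == 1.0
        assert kinetics.cell_score(adata, GeneProgram("none", ["z"]))["c0"] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3, size=(20, 6))
        adata = self._adata(X, [f"g{i}" for i in range(6)])
        prog = GeneProgram("p", ["g0", "g3"])
        s1 = kinetics.cell_score(adata, prog)
        s2 = kinetics.cell_score(self._adata(2 * X, [f"g{i}" for i in range(6)]), prog)
        assert np.allclose(s1.fillna(0), s2.fillna(0))

    def test_zero_count_cell_reported(self):
        adata = self._adata([[0, 0], [2, 2]], ["a", "b"])
        with pytest.warns(UserWarning):
            s = kinetics.cell_score(adata, GeneProgram("p", ["a"]))
        assert np.isnan(s["c0"]) and s["c1"] == 0.5


class TestLineageGeneSelection:
    def test_threshold_rules_on_crafted_model(self):
        e = pd.DataFrame(
            {
                0: [2 ** -10, 2 ** -14, 2 ** -6, 2 ** -11],
                1: [2 ** -10, 2 ** -9, 2 ** -9, 2 ** -9],
                2: [2 ** -10, 2 ** -9, 2 ** -11, 2 ** -6],
            },
            index=["constant", "dim", "a_gene", "b_gene"],
        )
        model = _model_from_e(e, {0: "A", 1: "mid", 2: "B"})
        stats = kinetics.select_lineage_variable_genes(
            model, ["A", "mid", "B"], ["A"], ["B"],
            LineageGeneFilterParams(min_range=2.0, min_endpoint_gap=1.5),
        )
        assert not stats.loc["constant", "selected"]  # zero range
        assert not stats.loc["dim", "selected"]  # min le < -13
        assert stats.loc["a_gene", "selected"] and stats.loc["a_gene", "side"] == "A"
        assert stats.loc["b_gene", "selected"] and stats.loc["b_gene", "side"] == "B"

    def test_planted_program_recovery(self, epc_seed1):
        """>= 90% of planted branch-program genes survive with correct side."""
        clusters = epc_seed1["clusters"]
        spt_prog = set(epc_seed1["programs"]["spt_gly_score"].genes)
        tgc_prog = set(epc_seed1["programs"]["tgc_progenitor_score"].genes)
        spt_truth = {f"SptG{i:02d}" for i in range(30)}
        tgc_truth = {f"TgcG{i:02d}" for i in range(30)}
        assert len(spt_prog & spt_truth) >= 27
        assert len(tgc_prog & tgc_truth) >= 27
        assert len(spt_prog & tgc_truth) == 0
        assert len(tgc_prog & spt_truth) == 0
        assert set(clusters.index) >= spt_truth | tgc_truth


class TestClusterLineageGenes:
    def _two_group_model(self, permute_seed=None):
        rng = np.random.default_rng(7)
        mcs = list(range(6))
        up = np.array([0.0, 0.2, 0.5, 1.0, 1.5, 2.0])
        genes, rows = [], []
        for i in range(10):
            genes.append(f"up{i}")
            rows.append(up + rng.normal(0, 0.05, 6))
        for i in range(10):
            genes.append(f"dn{i}")
            rows.append(-up + rng.normal(0, 0.05, 6))
        e = pd.DataFrame(2.0 ** np.array(rows) * 1e-3, index=genes, columns=mcs)
        order = genes if permute_seed is None else list(
            np.array(genes)[np.random.default_rng(permute_seed).permutation(len(genes))]
        )
        model = _model_from_e(e, {0: "A", 1: "A", 2: "mid", 3: "mid", 4: "B", 5: "B"})
        return model, order

    def test_anticorrelated_groups_separate(self):
        model, genes = self._two_group_model()
        clusters, programs = kinetics.cluster_lineage_genes(
            model, genes, ["A", "mid", "B"], ["A"], ["B"], n_clusters=2
        )
        groups = {c: set(clusters.index[clusters == c]) for c in clusters.unique()}
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(f"dn{i}" for i in range(10)),
            frozenset(f"up{i}" for i in range(10)),
        }

    def test_gene_order_invariance(self):
        model, genes = self._two_group_model()
        _, p1 = kinetics.cluster_lineage_genes(
            model, genes, ["A", "mid", "B"], ["A"], ["B"], n_clusters=2, seed=3
        )
        _, p2 = kinetics.cluster_lineage_genes(
            model, list(reversed(genes)), ["A", "mid", "B"], ["A"], ["B"], n_clusters=2, seed=3
        )
        assert p1["endpoint_a"].genes == p2["endpoint_a"].genes
        assert p1["endpoint_b"].genes == p2["endpoint_b"].genes

    def test_five_archetypes_recovered(self):
        """k-means on relative profiles recovers planted archetypes (ARI)."""
        rng = np.random.default_rng(11)
        mcs = list(range(10))
        x = np.linspace(0, 1, 10)
        archetypes = [2 * x, -2 * x, 2 * np.abs(x - 0.5), np.where(x < 0.5, 1.0, -1.0), np.zeros(10)]
        genes, rows, truth = [], [], []
        for a, arch in enumerate(archetypes):
            for i in range(12):
                genes.append(f"a{a}_{i}")
                rows.append(arch + rng.normal(0, 0.08, 10))
                truth.append(a)
        e = pd.DataFrame(2.0 ** np.array(rows) * 1e-3, index=genes, columns=mcs)
        ct = {m: ("A" if m < 2 else "B" if m > 7 else "mid") for m in mcs}
        model = _model_from_e(e, ct)
        clusters, _ = kinetics.cluster_lineage_genes(
            model, genes, ["A", "mid", "B"], ["A"], ["B"], n_clusters=5, seed=2
        )
        ari = adjusted_rand_score(truth, clusters.reindex(genes))
        assert ari >= 0.9

    def test_too_few_genes_raises(self):
        model, genes = self._two_group_model()
        with pytest.raises(ValueError):
            kinetics.cluster_lineage_genes(model, genes[:3], ["A"], ["A"], ["B"], n_clusters=5)


class TestPrincipalCurve:
    def test_straight_line_recovers_linear_coordinate(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 1, 200))
        X = pd.DataFrame({"x": t, "y": 0.5 * t}, index=[f"c{i}" for i in range(200)])
        anchor = pd.Series(t < 0.1, index=X.index)
        traj = kinetics.fit_principal_curve(X, anchor)
        pos = traj.cell_position
        assert spearmanr(pos, t).statistic == pytest.approx(1.0)
        interior = (t > 0.05) & (t < 0.95)
        lin = (t - t.min()) / (t.max() - t.min())
        assert np.corrcoef(pos[interior], lin[interior])[0, 1] > 0.999

    def test_axis_flip_invariance(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 1, 150))
        X = pd.DataFrame(
            {"x": t + rng.normal(0, 0.02, 150), "y": t**2 + rng.normal(0, 0.02, 150)},
            index=[f"c{i}" for i in range(150)],
        )
        anchor = pd.Series(t < 0.1, index=X.index)
        p1 = kinetics.fit_principal_curve(X, anchor).cell_position
        p2 = kinetics.fit_principal_curve(X[["y", "x"]], anchor).cell_position
        assert np.corrcoef(p1, p2)[0, 1] > 0.99

    def test_s_shaped_arc_orders_cells(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 1, 500))
        X = pd.DataFrame(
            {
                "x": t + rng.normal(0, 0.03, 500),
                "y": np.sin(2.5 * t) + rng.normal(0, 0.03, 500),
            },
            index=[f"c{i}" for i in range(500)],
        )
        anchor = pd.Series(t < 0.05, index=X.index)
        traj = kinetics.fit_principal_curve(X, anchor)
        assert abs(spearmanr(traj.cell_position, t).statistic) >= 0.95

    def test_collinear_fallback(self):
        t = np.linspace(0, 1, 60)
        X = pd.DataFrame({"x": t, "y": 2 * t}, index=[f"c{i}" for i in range(60)])
        anchor = pd.Series(t < 0.1, index=X.index)
        with pytest.warns(UserWarning):
            traj = kinetics.fit_principal_curve(X, anchor)
        assert spearmanr(traj.cell_position, t).statistic == pytest.approx(1.0)

    def test_too_few_cells_raises(self):
        X = pd.DataFrame({"x": [0, 1], "y": [0, 1]})
        with pytest.raises(ValueError):
            kinetics.fit_principal_curve(X, pd.Series([True, False]))


class TestPseudotimeKinetics:
    def test_constant_gene_flat_profile(self):
        rng = np.random.default_rng(4)
        n = 240
        t = np.sort(rng.uniform(0, 1, n))
        X = np.column_stack([np.full(n, 5), rng.poisson(5, n)]).astype(np.int64)
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
            var=pd.DataFrame(index=["const", "noise"]),
        )
        scores = pd.DataFrame({"x": t, "y": 0.3 * t}, index=adata.obs_names)
        traj = kinetics.fit_principal_curve(scores, pd.Series(t < 0.1, index=adata.obs_names))
        kin = kinetics.pseudotime_kinetics(traj, adata, ["const"])
        vals = kin["e"].loc["const"].dropna()
        assert vals.std() / vals.mean() < 0.15
        assert kin["midpoint_bin"] == 7

    def test_planted_decline_monotone(self, epc_seed1):
        kin = epc_seed1["detail"]["hand1"]["kinetics"]
        prof = kin["e"].loc["Hand1like"].dropna()
        tau, p = kendalltau(prof.index, prof.to_numpy())
        assert tau < 0 and p < 0.05

    def test_endpoint_fold_within_band(self, epc_seed1):
        assert epc_seed1["hand1_fold"] == pytest.approx(12.0, rel=0.25)
        assert epc_seed1["ascl2_fold"] == pytest.approx(7.0, rel=0.25)


class TestPGCPrecursors:
    def _setup(self):
        e = pd.DataFrame(
            np.full((3, 5), 0.2), index=["g1", "g2", "g3"], columns=range(5)
        )
        model = _model_from_e(
            e, {0: "pgc", 1: "pgc", 2: "exm", 3: "exm", 4: "exm"}
        )
        # per-cell scores/Et: one cell per metacell via _model_from_e
        score = pd.Series(
            {"cell0": 0.9, "cell1": 0.8, "cell2": 0.5, "cell3": 0.1, "cell4": 0.5}
        )
        et = pd.Series(
            {"cell0": 7.0, "cell1": 7.0, "cell2": 7.0, "cell3": 7.0, "cell4": 9.0}
        )
        return model, score, et

    def test_intermediate_and_early_flagged(self):
        model, score, et = self._setup()
        res = kinetics.identify_exm_pgc_precursors(
            model, score, et, ["pgc"], et_max=8.0,
            source=pd.Series("atlas", index=score.index),
        )
        assert res["metacells"] == [2]  # intermediate score, early time
        assert res["composition"].sum() == pytest.approx(1.0)

    def test_pgc_level_score_not_flagged(self):
        model, score, et = self._setup()
        res = kinetics.identify_exm_pgc_precursors(model, score, et, ["pgc"], et_max=8.0)
        assert 0 not in res["metacells"] and 1 not in res["metacells"]

    def test_late_intermediate_not_flagged(self):
        model, score, et = self._setup()
        res = kinetics.identify_exm_pgc_precursors(model, score, et, ["pgc"], et_max=8.0)
        assert 4 not in res["metacells"]  # same score as mc 2 but Et = 9
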