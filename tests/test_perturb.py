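"""Projection, DE statistics, lateral screening and composition tests."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from embryochrono import perturb
from embryochrono.atlas import MetacellModel
from embryochrono.perturb import LFC_EPSILON

from conftest import holdout_result


def _model_from_e(e: pd.DataFrame, celltype: dict) -> MetacellModel:
    le = np.log2(e + 1e-5)
    lf = le.sub(le.mean(axis=1), axis=0)
    part = pd.Series({f"cell{m}": m for m in e.columns})
    return MetacellModel(partition=part, e=e, le=le, lf=lf, celltype=pd.Series(celltype))


class TestChisqDE:
    def test_identical_proportions_null(self):
        g1 = pd.Series({"a": 10, "b": 90})
        g2 = pd.Series({"a": 30, "b": 270})
        res = perturb.chisq_de(g1, g2)
        assert res.loc["a", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["a", "p"] == pytest.approx(1.0)

    def test_statistic_matches_observed_expected_oracle(self):
        """chi2 = sum (O-E)^2/E over the 2x2 table, computed independently."""
        g1 = pd.Series({"g": 10, "rest": 990})
        g2 = pd.Series({"g": 30, "rest": 970})
        res = perturb.chisq_de(g1, g2)
        table = np.array([[10.0, 990.0], [30.0, 970.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert res.loc["g", "statistic"] == pytest.approx(oracle, abs=1e-9)

    def test_zero_both_groups_excluded(self):
        g1 = pd.Series({"a": 0, "b": 100})
        g2 = pd.Series({"a": 0, "b": 100})
        res = perturb.chisq_de(g1, g2)
        assert np.isnan(res.loc["a", "p"])

    def test_bh_contract(self):
        rng = np.random.default_rng(0)
        g1 = pd.Series(rng.poisson(50, 100), index=[f"g{i}" for i in range(100)])
        g2 = pd.Series(rng.poisson(50, 100), index=g1.index)
        res = perturb.chisq_de(g1, g2).dropna()
        assert (res.q >= res.p - 1e-12).all()
        assert res.p.between(0, 1).all()

    def test_type_i_error_calibration(self):
        from embryochrono.pipelines import chisq_null_calibration

        res = chisq_null_calibration(seed=5)
        assert abs(res["frac_p_lt_05"] - 0.05) <= 0.02


class TestLfc:
    def _tables(self, q_val, p_val):
        genes = ["g"]
        e_q = pd.DataFrame({0: [q_val]}, index=genes)
        e_p = pd.DataFrame({0: [p_val]}, index=genes)
        groups = pd.DataFrame(
            {"celltype": ["t"], "condition": ["b"], "metacell": [0]}, index=["c0"]
        )
        return groups, e_q, e_p

    def test_identical_profiles_zero(self):
        groups, e_q, e_p = self._tables(0.1, 0.1)
        lfc, n = perturb.lfc_vs_projection(groups, e_q, e_p)
        assert lfc.loc["g", "b|t"] == pytest.approx(0.0, abs=1e-12)
        assert n["b|t"] == 1

    def test_closed_form_single_cell(self):
        groups, e_q, e_p = self._tables(0.1, 0.05)
        lfc, _ = perturb.lfc_vs_projection(groups, e_q, e_p)
        oracle = np.log2(0.1 + 5e-5) - np.log2(0.05 + 5e-5)
        assert lfc.loc["g", "b|t"] == pytest.approx(oracle, abs=1e-12)

    def test_epsilon_guard_on_zeroed_gene(self):
        groups, e_q, e_p = self._tables(0.0, 0.01)
        lfc, _ = perturb.lfc_vs_projection(groups, e_q, e_p)
        oracle = np.log2(5e-5) - np.log2(0.01 + 5e-5)
        assert lfc.loc["g", "b|t"] == pytest.approx(oracle, abs=1e-12)

    def test_exact_antisymmetry(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(30)]
        e_q = pd.DataFrame({0: rng.dirichlet(np.ones(30)), 1: rng.dirichlet(np.ones(30))}, index=genes)
        e_p = pd.DataFrame({0: rng.dirichlet(np.ones(30)), 1: rng.dirichlet(np.ones(30))}, index=genes)
        groups = pd.DataFrame(
            {"celltype": ["t", "t", "u"], "condition": ["b", "b", "b"], "metacell": [0, 1, 1]},
            index=["c0", "c1", "c2"],
        )
        fwd, _ = perturb.lfc_vs_projection(groups, e_q, e_p)
        rev, _ = perturb.lfc_vs_projection(groups, e_p, e_q)
        assert np.allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)

    def test_epsilon_value(self):
        assert LFC_EPSILON == 5e-5


class TestFallbackAnnotation:
    def _model(self):
        e = pd.DataFrame(
            {0: [0.6, 0.3, 0.1], 1: [0.1, 0.3, 0.6]}, index=["a", "b", "c"]
        )
        return _model_from_e(e, {0: "alpha", 1: "beta"})

    def _query(self, counts, genes):
        return ad.AnnData(
            X=np.asarray(counts, dtype=np.int64),
            obs=pd.DataFrame(index=[f"q{i}" for i in range(len(counts))]),
            var=pd.DataFrame(index=genes),
        )

    def test_rescaled_profile_wins(self):
        model = self._model()
        query = self._query([[60, 30, 10]], ["a", "b", "c"])
        out = perturb.fallback_correlation_annotation(query, model, ["a", "b", "c"])
        assert out["q0"] == "alpha"

    def test_feature_list_defines_the_computation(self):
        model = self._model()
        q1 = self._query([[60, 30, 10]], ["a", "b", "c"])
        q2 = self._query([[60, 30, 10, 500]], ["a", "b", "c", "offlist"])
        o1 = perturb.fallback_correlation_annotation(q1, model, ["a", "b", "c"])
        o2 = perturb.fallback_correlation_annotation(q2, model, ["a", "b", "c"])
        assert o1["q0"] == o2["q0"]

    def test_hand_pearson_argmax(self):
        model = self._model()
        query = self._query([[5, 10, 30]], ["a", "b", "c"])
        u = np.log2(np.array([5, 10, 30]) + 1.0)
        best, best_r = None, -np.inf
        for m in [0, 1]:
            v = np.log2(model.e[m].to_numpy() + 1e-5)
            r = np.corrcoef(u, v)[0, 1]
            if r > best_r:
                best, best_r = m, r
        out = perturb.fallback_correlation_annotation(query, model, ["a", "b", "c"])
        assert out["q0"] == model.celltype[best]

    def test_zero_variance_unassigned(self):
        model = self._model()
        query = self._query([[0, 0, 0]], ["a", "b", "c"])
        out = perturb.fallback_correlation_annotation(query, model, ["a", "b", "c"])
        assert out["q0"] == ""


class TestAnnotation:
    def test_held_out_accuracy(self, holdout_seed1):
        assert holdout_seed1["accuracy"] >= 0.95

    def test_duplicated_atlas_cell_inherits_type(self, holdout_seed1):
        """A query cell copying an atlas cell lands on that cell's type."""
        ref = holdout_seed1["reference"]
        model = holdout_seed1["model"]
        feats = holdout_seed1["features"]
        pick = ref.counts.obs_names[[0, 57, 113]]
        query = ref.counts[list(pick)].copy()
        query.obs_names = [f"dup{i}" for i in range(3)]
        proj = perturb.annotate_query_cells(
            query, ref.counts, model, ref.counts.obs["true_state"], feats
        )
        truth = ref.counts.obs.loc[pick, "true_state"].to_numpy()
        assert (proj.cell_annotation.to_numpy() == truth).all()


class TestProjection:
    def test_identical_metacell_projects_to_itself(self, holdout_seed1):
        model = holdout_seed1["model"]
        feats = holdout_seed1["features"]
        assignment, e_proj = perturb.project_query_metacells(model, model, feats)
        assert (assignment.index == assignment["atlas_metacell"]).all()
        assert np.allclose(e_proj.sum(axis=0), 1.0, atol=1e-9)


class TestTiming:
    def test_single_cell_embryo_unmatched(self, holdout_seed1):
        ref = holdout_seed1["reference"]
        feats = holdout_seed1["features"]
        query = ref.counts[[0]].copy()
        query.obs["embryo"] = "lonely"
        rank = pd.Series(
            np.arange(1, ref.embryos.shape[0] + 1), index=ref.embryos["embryo"]
        )
        matched = perturb.time_query_embryos(query, ref.counts, rank, feats)
        assert np.isnan(matched["lonely"])

    def test_self_match_within_two_ranks(self):
        from embryochrono.pipelines import embryo_self_match

        assert embryo_self_match(seed=1)["max_abs_delta"] <= 2

    def test_batch_window_matching(self):
        rng = np.random.default_rng(2)
        n_emb, n_mc = 30, 15
        centers = np.linspace(0, n_mc - 1, n_emb)
        freq = np.exp(-0.5 * ((np.arange(n_mc)[None, :] - centers[:, None]) / 2.0) ** 2)
        freq = freq / freq.sum(axis=1, keepdims=True)
        per_embryo = pd.DataFrame(freq, index=[f"e{i}" for i in range(n_emb)])
        rank = pd.Series(np.arange(1, n_emb + 1), index=per_embryo.index)
        batch = per_embryo.iloc[12] + rng.normal(0, 0.002, n_mc)
        best = perturb.match_batch_to_rank(batch, per_embryo, rank, window=3)
        assert abs(rank[best] - 13) <= 2


class TestLateralScreen:
    def test_below_threshold_not_candidate(self):
        lfc = pd.DataFrame(
            {"ko|t": [0.5, 1.5], "ctrl|t": [0.0, 0.1]}, index=["weak", "strong"]
        )
        out = perturb.screen_lateral_genes(lfc, ["ctrl"], n_clusters=1)
        assert not out.loc["weak", "candidate"]
        assert out.loc["strong", "candidate"]

    def test_planted_nuisance_flagged_targets_spared(self, ko_seed1):
        assert ko_seed1["lateral_recall"] >= 0.9
        assert ko_seed1["target_lateral_rate"] <= 0.1


class TestPerEmbryoDE:
    def test_fold_thresholds(self):
        genes = ["two_fold", "flat", "strong"]
        fq = {("e1", "t"): pd.Series([2e-3, 1e-3, 9e-3], index=genes)}
        fw = {("e1", "t"): pd.Series([1e-3, 1e-3, 1e-3], index=genes)}
        out = perturb.per_embryo_celltype_de(fq, fw)
        assert not out.loc["two_fold", "selected"]  # below 3-fold
        assert not out.loc["flat", "selected"]
        assert out.loc["strong", "selected"]

    def test_planted_recovery_end_to_end(self, ko_seed1):
        assert ko_seed1["de_sensitivity"] >= 0.9


class TestCompositionTests:
    def test_identical_groups(self):
        comp = pd.DataFrame(
            {"x": [0.4, 0.5, 0.6], "y": [0.6, 0.5, 0.4]}, index=["e1", "e2", "e3"]
        )
        res = perturb.compare_celltype_frequencies(comp, comp.copy(), mode="per_embryo")
        assert (res["p"] == 1.0).all()
        cells = pd.Series({"x": 50, "y": 50})
        ratios = perturb.compare_celltype_frequencies(
            comp, comp.copy(), mode="pooled_ratio", cells1=cells, cells2=cells
        )
        assert np.allclose(ratios["log2_ratio"], 0.0)

    def test_pooled_chisq_oracle(self):
        comp = pd.DataFrame({"x": [1.0]}, index=["e"])
        cells1 = pd.Series({"pgc": 5, "rest": 995})
        cells2 = pd.Series({"pgc": 20, "rest": 980})
        res = perturb.compare_celltype_frequencies(
            comp, comp.copy(), mode="pooled_lowfreq", cells1=cells1, cells2=cells2
        )
        table = np.array([[5.0, 995.0], [20.0, 980.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert res.loc["pgc", "statistic"] == pytest.approx(oracle, abs=1e-9)

    def test_composition_must_sum_to_one(self):
        comp = pd.DataFrame({"x": [0.4], "y": [0.5]}, index=["e"])
        with pytest.raises(ValueError):
            perturb.compare_celltype_frequencies(comp, comp, mode="per_embryo")

    def test_planted_shift_detected(self, ko_seed1):
        ft = ko_seed1["freq_tests"]
        for state, realized in ko_seed1["realized_freq_folds"].items():
            assert ft.loc[state, "q"] < 0.05
            direction = np.sign(ft.loc[state, "median1"] - ft.loc[state, "median2"])
            assert direction == np.sign(np.log(realized))

    def test_exe_ratio(self):
        meta = pd.DataFrame(
            {
                "embryo": ["a"] * 4 + ["b"] * 4,
                "celltype": ["exe", "exe", "emb", "emb", "exe", "emb", "emb", "emb"],
            }
        )
        bins = pd.Series({"a": 1, "b": 2})
        ratio = perturb.exe_embryonic_ratio(meta, bins, exe_types=["exe"])
        assert ratio[1] == pytest.approx(1.0)
        assert ratio[2] == pytest.approx(1 / 3)
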