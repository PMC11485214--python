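"""End-to-end workflows over synthetic cohorts.

Each function runs a full multi-stage pipeline on a generated cohort and
returns the recovered quantities next to the planted ground truth, so the
same code path backs the analysis drivers, the test suite and the
reproduction script.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import atlas, chrono, kinetics, perturb, qc, syndata


def _substream(seed: int, label: str) -> int:
    """Derive a stable per-stage seed below 2**31 from a root seed."""
    h = np.random.SeedSequence([seed, zlib.crc32(label.encode()) % (2**31)])
    return int(h.generate_state(1)[0] % (2**31))


def build_annotated_model(
    cohort: syndata.SyntheticCohort,
    seed: int,
    Knn: int = 100,
    min_size: int = 20,
    target_size: int = 60,
    lateral_markers: dict[str, list[str]] | None = None,
) -> tuple[atlas.MetacellModel, list[str]]:
    """Feature selection + metacell construction + truth-majority annotation.

    The synthetic truth labels stand in for the expert cell-type curation a
    real atlas would use.
    """
    feats, _ = atlas.select_feature_genes(
        cohort.counts, lateral_markers=lateral_markers, seed=seed
    )
    model = atlas.build_metacells(
        cohort.counts, feats, Knn=Knn, min_size=min_size, target_size=target_size, seed=seed
    )
    model.annotate(cohort.counts.obs["true_state"])
    return model, feats


# ---------------------------------------------------------------------- #
# EPC bifurcation fold-change recovery
# ---------------------------------------------------------------------- #


def epc_fold_recovery(
    seed: int,
    hand1_fold: float = 12.0,
    ascl2_fold: float = 7.0,
    n_embryos: int = 12,
) -> dict:
    """Recover planted endpoint fold-changes through the lineage pipeline.

    Generates a bifurcating EPC-like cohort with a Hand1-like gene planted at
    ``hand1_fold`` repression towards the SpT-Gly endpoint and an Ascl2-like
    gene at ``ascl2_fold`` towards the TGC endpoint, then runs variable-gene
    selection, program clustering, single-cell scoring, principal-curve
    fitting and 12-bin kinetics on each branch, reporting the first/last bin
    expression ratios.
    """
    spec = syndata.epc_cohort_spec(
        n_embryos=n_embryos, hand1_fold=hand1_fold, ascl2_fold=ascl2_fold, seed=seed
    )
    cohort = syndata.generate_atlas_cohort(spec)
    model, _ = build_annotated_model(cohort, seed=_substream(seed, "atlas"))

    spt_branch = ["uncommitted"] + [f"spt_i{k}" for k in range(1, 8)] + ["spt_gly"]
    tgc_branch = ["uncommitted"] + [f"tgc_i{k}" for k in range(1, 8)] + ["tgc_prog"]
    lineage = sorted(set(spt_branch) | set(tgc_branch))
    stats = kinetics.select_lineage_variable_genes(
        model, lineage, endpoint_a=["spt_gly"], endpoint_b=["tgc_prog"]
    )
    selected = list(stats.index[stats.selected])
    clusters, programs = kinetics.cluster_lineage_genes(
        model,
        selected,
        lineage,
        endpoint_a=["spt_gly"],
        endpoint_b=["tgc_prog"],
        program_names=("spt_gly_score", "tgc_progenitor_score"),
        seed=_substream(seed, "kmeans"),
    )
    spt_score = kinetics.cell_score(cohort.counts, programs["spt_gly_score"])
    tgc_score = kinetics.cell_score(cohort.counts, programs["tgc_progenitor_score"])
    scores = pd.DataFrame({"tgc": tgc_score, "spt": spt_score})
    cell_type = model.partition.map(model.celltype)

    folds = {}
    branch_defs = {
        "hand1": (spt_branch, "Hand1like"),
        "ascl2": (tgc_branch, "Ascl2like"),
    }
    for label, (branch_states, gene) in branch_defs.items():
        mask = cell_type.isin(branch_states)
        cells = list(cell_type.index[mask])
        branch = cohort.counts[cells]
        anchor = cell_type.loc[cells] == "uncommitted"
        traj = kinetics.fit_principal_curve(
            scores.loc[cells], anchor_a=anchor, seed=_substream(seed, f"curve_{label}")
        )
        kin = kinetics.pseudotime_kinetics(traj, branch, [gene])
        folds[label] = {
            "fold": kinetics.endpoint_fold(kin, gene),
            "n_cells": len(cells),
            "kinetics": kin,
            "trajectory": traj,
        }
    return {
        "hand1_fold": folds["hand1"]["fold"],
        "ascl2_fold": folds["ascl2"]["fold"],
        "planted": {"hand1": hand1_fold, "ascl2": ascl2_fold},
        "n_cells": cohort.counts.n_obs,
        "n_selected_genes": len(selected),
        "clusters": clusters,
        "programs": programs,
        "scores": scores,
        "detail": folds,
    }


# ---------------------------------------------------------------------- #
# temporal ordering recovery
# ---------------------------------------------------------------------- #


def ordering_recovery(seed: int, n_embryos: int = 30) -> dict:
    """Order a synthetic cohort's embryos and compare ranks with truth."""
    spec = syndata.default_atlas_spec(n_embryos=n_embryos, seed=seed)
    cohort = syndata.generate_atlas_cohort(spec)
    model, _ = build_annotated_model(cohort, seed=_substream(seed, "atlas"))
    nominal = cohort.embryos.set_index("embryo")["nominal_day"]
    timeline = chrono.make_timeline(
        model,
        cohort.counts.obs["embryo"],
        nominal,
        n_bins=min(16, n_embryos),
        seed=_substream(seed, "order"),
    )
    true_time = cohort.embryos.set_index("embryo")["true_time"]
    rho = spearmanr(timeline.rank, true_time.reindex(timeline.rank.index)).statistic
    et_rmse = float(
        np.sqrt(np.mean((timeline.Et - true_time.reindex(timeline.Et.index)) ** 2))
    )
    nominal_rmse = float(
        np.sqrt(np.mean((nominal - true_time) ** 2))
    )
    return {
        "spearman": float(rho),
        "abs_spearman": float(abs(rho)),
        "timeline": timeline,
        "true_time": true_time,
        "et_rmse": et_rmse,
        "nominal_rmse": nominal_rmse,
        "cohort": cohort,
        "model": model,
    }


# ---------------------------------------------------------------------- #
# projection / annotation accuracy
# ---------------------------------------------------------------------- #


def held_out_annotation(seed: int, holdout_frac: float = 0.2) -> dict:
    """Re-annotate held-out synthetic atlas cells through the projection path."""
    spec = syndata.default_atlas_spec(seed=seed)
    cohort = syndata.generate_atlas_cohort(spec)
    rng = np.random.default_rng(_substream(seed, "holdout"))
    n = cohort.counts.n_obs
    held = np.zeros(n, dtype=bool)
    held[rng.choice(n, size=int(round(holdout_frac * n)), replace=False)] = True
    ref = syndata.SyntheticCohort(
        counts=cohort.counts[~held].copy(), embryos=cohort.embryos
    )
    query = cohort.counts[held].copy()

    model, feats = build_annotated_model(ref, seed=_substream(seed, "atlas"))
    atlas_celltype = ref.counts.obs["true_state"]
    proj = perturb.annotate_query_cells(
        query, ref.counts, model, atlas_celltype, feats, K=100
    )
    truth = query.obs["true_state"]
    assigned = proj.cell_annotation != ""
    acc = float((proj.cell_annotation[assigned] == truth[assigned]).mean())
    return {
        "accuracy": acc,
        "n_query": int(held.sum()),
        "n_unassigned": int((~assigned).sum()),
        "fallback_used": int(proj.fallback.sum()),
        "projection": proj,
        "model": model,
        "features": feats,
        "reference": ref,
        "query": query,
    }


def embryo_self_match(seed: int) -> dict:
    """Time copies of WT embryos through the query-timing path.

    Each query embryo duplicates one atlas embryo's cells; the matched WT
    rank should land within 2 rank units of the source embryo's own rank.
    """
    rec = ordering_recovery(seed, n_embryos=20)
    cohort, timeline = rec["cohort"], rec["timeline"]
    feats, _ = atlas.select_feature_genes(cohort.counts, seed=_substream(seed, "feat"))
    picks = list(timeline.rank.sort_values().index[4::5])  # a spread of source embryos
    deltas = {}
    for emb in picks:
        cells = cohort.counts.obs_names[cohort.counts.obs["embryo"] == emb]
        query = cohort.counts[list(cells)].copy()
        query.obs["embryo"] = f"copy_{emb}"
        matched = perturb.time_query_embryos(
            query, cohort.counts, timeline.rank, feats
        )
        deltas[emb] = float(abs(matched.iloc[0] - timeline.rank[emb]))
    return {"max_abs_delta": max(deltas.values()), "deltas": deltas}


# ---------------------------------------------------------------------- #
# KO end-to-end recovery
# ---------------------------------------------------------------------- #


def ko_recovery(
    seed: int,
    n_embryos_per_group: int = 10,
    target_scale: float = 0.15,
    nuisance_shift: float = 1.2,
    freq_effects: dict[str, float] | None = None,
) -> dict:
    """Full KO pipeline: projection, lateral screen, per-embryo DE, composition.

    Plants ~20 strong (>=3-fold) KO-responsive genes, 10 batch-restricted
    nuisance genes shared by the KO and its littermate controls, and
    state-frequency shifts, then measures DE sensitivity after lateral-gene
    removal and per-embryo Wilcoxon composition calls.
    """
    # multipliers chosen so the *realized* (renormalized) frequency shifts are
    # at least twofold for both affected states
    freq_effects = freq_effects or {"endoderm": 0.4, "chor_b3": 3.5}
    # perturbed embryos are collected over a narrow developmental window, as
    # in targeted KO experiments; the reference atlas spans the full range
    ko_window = (7.5, 8.5)
    design = _substream(seed, "design")
    base = syndata.default_atlas_spec(
        n_embryos=n_embryos_per_group, cells_per_embryo=(90, 130),
        seed=_substream(seed, "base"), design_seed=design,
    )
    resolved = base.resolved_expression()
    hk = [g for g in resolved.columns if g.startswith("Hk")]
    baseline = resolved[hk].mean(axis=0).sort_values(ascending=False)
    target_genes = list(baseline.index[:20])
    nuisance_genes = list(baseline.index[20:30])

    wt_spec = syndata.default_atlas_spec(
        n_embryos=20, cells_per_embryo=(90, 130),
        seed=_substream(seed, "wt"), design_seed=design,
    )
    wt = syndata.generate_atlas_cohort(wt_spec, condition="wt")
    ko_spec = syndata.default_atlas_spec(
        n_embryos=n_embryos_per_group, cells_per_embryo=(90, 130),
        seed=_substream(seed, "ko"), design_seed=design,
    )
    ko_spec.latent_time_range = ko_window
    ko = syndata.generate_perturbation_cohort(
        ko_spec,
        syndata.KOSpec(
            target_genes={g: target_scale for g in target_genes},
            frequency_multipliers=freq_effects,
            nuisance_genes={g: nuisance_shift for g in nuisance_genes},
            condition="ko",
        ),
    )
    ctrl_spec = syndata.default_atlas_spec(
        n_embryos=n_embryos_per_group, cells_per_embryo=(90, 130),
        seed=_substream(seed, "ctrl"), design_seed=design,
    )
    ctrl_spec.latent_time_range = ko_window
    ctrl = syndata.generate_perturbation_cohort(
        ctrl_spec,
        syndata.KOSpec(
            nuisance_genes={g: nuisance_shift for g in nuisance_genes}, condition="ctrl"
        ),
    )
    for name, cohort in [("ko", ko), ("ctrl", ctrl)]:
        cohort.counts.obs["embryo"] = f"{name}_" + cohort.counts.obs["embryo"].astype(str)
        cohort.counts.obs_names = f"{name}_" + cohort.counts.obs_names.astype(str)

    model, feats = build_annotated_model(wt, seed=_substream(seed, "atlas"))
    proj_feats = [g for g in feats if g not in target_genes and g not in nuisance_genes]

    # metacells are built per condition: pooling KO and control cells into
    # shared metacells would leak the ablation into control profiles
    lfc_parts, n_parts, type_parts, expr_parts = [], [], [], []
    for cond, cohort in [("ko", ko), ("ctrl", ctrl)]:
        q_model = atlas.build_metacells(
            cohort.counts, proj_feats, Knn=100, min_size=20, target_size=60,
            seed=_substream(seed, f"qmc_{cond}"),
        )
        assignment, e_proj = perturb.project_query_metacells(q_model, model, proj_feats)
        cell_mc = q_model.partition
        cell_type = cell_mc.map(assignment["atlas_celltype"])
        type_parts.append(cell_type)
        cell_groups = pd.DataFrame(
            {"celltype": cell_type, "condition": cond, "metacell": cell_mc}
        )
        shared = e_proj.index
        e_query = q_model.e.loc[shared]
        e_query = e_query / e_query.sum(axis=0)
        part_lfc, part_n = perturb.lfc_vs_projection(cell_groups, e_query, e_proj)
        lfc_parts.append(part_lfc)
        n_parts.append(part_n)
        expr_parts.append(
            (q_model.e.loc[shared].max(axis=1) >= 1e-4) | (e_proj.max(axis=1) >= 1e-4)
        )
    lfc = pd.concat(lfc_parts, axis=1)
    n_bt = pd.concat(n_parts)
    cell_type = pd.concat(type_parts)
    expr_pass = pd.concat(expr_parts, axis=1).any(axis=1)
    lateral = perturb.screen_lateral_genes(
        lfc, control_conditions=["ctrl"], expr_pass=expr_pass,
        seed=_substream(seed, "lat"),
    )
    lateral_set = set(lateral.index[lateral.lateral])

    # per-embryo, per-cell-type DE of KO vs pooled WT
    wt_type = wt.counts.obs["true_state"]
    f_wt = {}
    wt_X = wt.counts.X
    for t in wt_type.unique():
        mask = (wt_type == t).to_numpy()
        pooled = np.asarray(wt_X[mask].sum(axis=0)).ravel()
        tot = pooled.sum()
        if tot > 0:
            f_wt[t] = pd.Series(pooled / tot, index=wt.counts.var_names)
    f_query, cells_per_group = {}, {}
    ko_emb = ko.counts.obs["embryo"]
    ko_type = cell_type.reindex(ko.counts.obs_names)
    for emb in ko_emb.unique():
        for t in pd.unique(ko_type.dropna()):
            mask = ((ko_emb == emb) & (ko_type == t)).to_numpy()
            if mask.sum() == 0 or t not in f_wt:
                continue
            pooled = np.asarray(ko.counts.X[mask].sum(axis=0)).ravel()
            f_query[(emb, t)] = pd.Series(pooled / pooled.sum(), index=ko.counts.var_names)
            f_wt[(emb, t)] = f_wt[t]
            cells_per_group[(emb, t)] = int(mask.sum())
    de = perturb.per_embryo_celltype_de(
        {k: v for k, v in f_query.items()},
        {k: f_wt[k] for k in f_query},
        cells_per_group=pd.Series(cells_per_group),
        lateral_genes=lateral_set,
        seed=_substream(seed, "de"),
    )
    recovered = set(de.index[de.selected])
    sensitivity = len(recovered & set(target_genes)) / len(target_genes)
    lateral_recall = len(lateral_set & set(nuisance_genes)) / len(nuisance_genes)
    target_lateral_rate = len(lateral_set & set(target_genes)) / len(target_genes)

    # composition: per-embryo annotated frequencies, KO vs control
    all_embryo = pd.concat([ko.counts.obs["embryo"], ctrl.counts.obs["embryo"]])
    comp = (
        pd.DataFrame({"embryo": all_embryo, "celltype": cell_type})
        .dropna()
        .groupby(["embryo", "celltype"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    comp = comp.div(comp.sum(axis=1), axis=0)
    ko_comp = comp.loc[[e for e in comp.index if e.startswith("ko_")]]
    ctrl_comp = comp.loc[[e for e in comp.index if e.startswith("ctrl_")]]
    freq_tests = perturb.compare_celltype_frequencies(ko_comp, ctrl_comp, mode="per_embryo")

    # realized (renormalized) planted fold per affected state, averaged over
    # the collection window: multiplier / (1 + sum_i (m_i - 1) * s_i)
    t_grid = np.linspace(*ko_window, 9)
    realized = {}
    for state, m in freq_effects.items():
        shares = []
        for t in t_grid:
            p_states = {st.name: ko_spec.state_frequency_curves[st.name](t) for st in base.states}
            denom = 1.0 + sum((freq_effects.get(n, 1.0) - 1.0) * p for n, p in p_states.items())
            shares.append(m / denom)
        realized[state] = float(np.mean(shares))

    return {
        "de_sensitivity": sensitivity,
        "lateral_recall": lateral_recall,
        "target_lateral_rate": target_lateral_rate,
        "freq_tests": freq_tests,
        "planted_freq_effects": freq_effects,
        "realized_freq_folds": realized,
        "target_genes": target_genes,
        "nuisance_genes": nuisance_genes,
        "lateral": lateral,
        "de": de,
        "lfc": lfc,
        "n_bt": n_bt,
    }


# ---------------------------------------------------------------------- #
# QC calibrations
# ---------------------------------------------------------------------- #


def doublet_detection_auroc(seed: int, n_embryos: int = 4, rate: float = 0.1) -> dict:
    """pANN AUROC against spiked true doublets on a two-state cohort."""
    spec = syndata.default_atlas_spec(
        n_embryos=n_embryos, cells_per_embryo=(200, 250), seed=seed
    )
    # restrict to a two-state mixture so heterotypic doublets are detectable
    two = {"epc_a3": 0.5, "chor_b3": 0.5}
    spec.state_frequency_curves = {
        s.name: (lambda t, v=two.get(s.name, 0.0): v) for s in spec.states
    }
    cohort = syndata.generate_atlas_cohort(spec)
    spiked = syndata.spike_doublets(cohort, rate, seed=_substream(seed, "dbl"))
    scores = qc.doublet_scores(
        spiked.counts, qc.QCParams(pK=0.05), seed=_substream(seed, "pann")
    )
    truth = spiked.counts.obs["is_doublet"].to_numpy()
    from sklearn.metrics import roc_auc_score

    auroc = float(roc_auc_score(truth, scores.to_numpy()))
    return {"auroc": auroc, "scores": scores, "truth": truth, "cohort": spiked}


def chisq_null_calibration(seed: int, n_genes: int = 2000, depth: int = 200_000) -> dict:
    """Empirical type-I error of the chi-square DE test under the null."""
    rng = np.random.default_rng(seed)
    profile = np.exp(rng.normal(0, 1, n_genes))
    profile /= profile.sum()
    g1 = rng.multinomial(depth, profile)
    g2 = rng.multinomial(depth, profile)
    res = perturb.chisq_de(
        pd.Series(g1, index=[f"g{i}" for i in range(n_genes)]),
        pd.Series(g2, index=[f"g{i}" for i in range(n_genes)]),
    )
    tested = res.dropna(subset=["p"])
    frac = float((tested.p < 0.05).mean())
    return {"frac_p_lt_05": frac, "n_tested": len(tested), "result": res}
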