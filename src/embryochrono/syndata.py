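"""Synthetic multi-embryo UMI cohorts with known ground truth.

The generator emulates a cohort of individually barcoded embryos spanning a
latent developmental-time axis. Each embryo carries a latent time; each cell
draws a discrete state from time-dependent state-frequency curves; UMIs are
drawn from a multinomial over the state's mean expression vector, with an
optional per-cell/per-gene gamma multiplier providing negative-binomial-like
overdispersion typical of shallow UMI sampling. Ground truth (state, latent
time, program membership, doublet flags, planted effects) ships alongside the
counts so downstream stages can be validated without touching private state.

Two cohort builders cover the study designs the pipeline is exercised on:

* :func:`epc_cohort_spec` — a bifurcating ectoplacental-cone-like lineage
  (uncommitted progenitors splitting towards SpT-Gly-like and TGC-like
  fates) with a Hand1-like gene repressed 12-fold towards the SpT-Gly
  endpoint and an Ascl2-like gene repressed 7-fold towards the TGC endpoint.
* :func:`default_atlas_spec` — a small whole-atlas stand-in: two branching
  lineages plus a rare precursor state, cell-cycle gene programs and smooth
  state-frequency drift over latent time, suitable for embryo ordering and
  projection tests.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

# Paper-style cell-cycle marker symbols; the synthetic gene universe reuses
# them so cell-cycle scoring works unchanged on simulated cohorts.
from .markers import M_PHASE_GENES, S_PHASE_GENES


class SpecValidationError(ValueError):
    """Raised when a cohort spec violates an invariant; names the field."""


@dataclass
class StateSpec:
    """One discrete cell state.

    ``expression`` is the mean UMI-frequency vector over genes (normalized at
    resolution time). Alternatively a state may be declared as a geometric
    interpolation between two named states (``interpolate=(a, b, frac)``),
    which is resolved after planted fold-changes are applied so intermediate
    states inherit graded versions of every planted effect.
    """

    name: str
    lineage: str = ""
    expression: np.ndarray | None = None
    interpolate: tuple[str, str, float] | None = None


@dataclass
class CohortSpec:
    n_embryos: int
    cells_per_embryo: tuple[int, int]
    n_genes: int
    states: list[StateSpec]
    state_frequency_curves: Mapping[str, Callable[[float], float]]
    latent_time_range: tuple[float, float] = (5.5, 9.5)
    planted_foldchanges: dict[str, tuple[str, str, float]] = field(default_factory=dict)
    umi_depth: float = 2000.0
    depth_sigma: float = 0.5  # lognormal spread of per-cell depth (0 = Poisson only)
    doublet_rate: float = 0.0
    overdispersion_shape: float = 10.0
    gene_names: list[str] | None = None
    gene_programs: dict[str, str] = field(default_factory=dict)
    cell_cycle: tuple[list[str], float, float] | None = None  # (genes, boost, fraction)
    maturation: dict[str, float] | None = None  # gene -> log2 slope over the time window
    seed: int = 0

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.n_embryos < 1:
            raise SpecValidationError("n_embryos must be >= 1")
        lo, hi = self.cells_per_embryo
        if not (0 < lo <= hi):
            raise SpecValidationError("cells_per_embryo must be a positive range")
        if self.umi_depth <= 0:
            raise SpecValidationError("umi_depth must be > 0")
        if not (0.0 <= self.doublet_rate < 0.5):
            raise SpecValidationError("doublet_rate must be in [0, 0.5)")
        names = {s.name for s in self.states}
        if len(names) != len(self.states):
            raise SpecValidationError("states must have unique names")
        for s in self.states:
            if (s.expression is None) == (s.interpolate is None):
                raise SpecValidationError(
                    f"states[{s.name}] needs exactly one of expression/interpolate"
                )
            if s.expression is not None and len(s.expression) != self.n_genes:
                raise SpecValidationError(f"states[{s.name}] expression length != n_genes")
        for g, (a, b, f) in self.planted_foldchanges.items():
            if f <= 0:
                raise SpecValidationError(f"planted_foldchanges[{g}] fold must be > 0")
            if a not in names or b not in names:
                raise SpecValidationError(f"planted_foldchanges[{g}] references unknown state")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise SpecValidationError("gene_names length != n_genes")
        if self.maturation:
            genes = self.gene_index()
            for g in self.maturation:
                if g not in genes:
                    raise SpecValidationError(f"maturation references unknown gene {g!r}")
        # frequency curves must cover every state and sum to one over time
        missing = names - set(self.state_frequency_curves)
        if missing:
            raise SpecValidationError(f"state_frequency_curves missing states {sorted(missing)}")
        t0, t1 = self.latent_time_range
        for t in np.linspace(t0, t1, 9):
            tot = sum(self.state_frequency_curves[n](t) for n in names)
            if abs(tot - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"state_frequency_curves sum to {tot:.6f} != 1 at t={t:.3f}"
                )

    # ------------------------------------------------------------------ #
    def gene_index(self) -> pd.Index:
        if self.gene_names is not None:
            return pd.Index(self.gene_names)
        return pd.Index([f"g{i:04d}" for i in range(self.n_genes)])

    def resolved_expression(self) -> pd.DataFrame:
        """State mean-frequency matrix (states x genes) with planted folds applied.

        Planted fold-changes set end-state expression to start-state expression
        divided by the fold, then every explicit state is renormalized;
        interpolated states are resolved afterwards by geometric interpolation
        so planted effects decay smoothly along a branch.
        """
        genes = self.gene_index()
        expr: dict[str, np.ndarray] = {}
        for s in self.states:
            if s.expression is not None:
                expr[s.name] = np.asarray(s.expression, dtype=float).copy()
        for g, (a, b, fold) in self.planted_foldchanges.items():
            gi = genes.get_loc(g)
            if a in expr and b in expr:
                expr[b][gi] = expr[a][gi] / fold
        for name in expr:
            expr[name] = expr[name] / expr[name].sum()
        for s in self.states:
            if s.interpolate is not None:
                a, b, frac = s.interpolate
                pa, pb = expr[a], expr[b]
                mix = np.exp((1 - frac) * np.log(pa + 1e-12) + frac * np.log(pb + 1e-12))
                expr[s.name] = mix / mix.sum()
        order = [s.name for s in self.states]
        return pd.DataFrame(np.vstack([expr[n] for n in order]), index=order, columns=genes)


@dataclass
class SyntheticCohort:
    """Counts plus complete ground truth for a simulated cohort."""

    counts: ad.AnnData  # cells x genes, integer CSR; obs carries truth columns
    embryos: pd.DataFrame  # embryo, true_time, n_cells

    @property
    def truth(self) -> pd.DataFrame:
        return self.counts.obs


# ---------------------------------------------------------------------- #
# generation
# ---------------------------------------------------------------------- #


def _state_probs(spec: CohortSpec, t: float) -> np.ndarray:
    p = np.array([spec.state_frequency_curves[s.name](t) for s in spec.states], dtype=float)
    return p / p.sum()


def generate_atlas_cohort(spec: CohortSpec, condition: str = "WT") -> SyntheticCohort:
    """Simulate a wild-type-style cohort from a validated spec.

    Per-embryo latent times are drawn uniformly over ``latent_time_range`` and
    sorted so embryo IDs follow the time axis; each cell draws its state from
    the frequency curves at its embryo's time, a depth from a Poisson around
    ``umi_depth``, and counts from a (gamma-perturbed) multinomial. The whole
    draw is a pure function of ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.latent_time_range
    times = np.sort(rng.uniform(t0, t1, size=spec.n_embryos))
    lo, hi = spec.cells_per_embryo
    n_cells_per = rng.integers(lo, hi + 1, size=spec.n_embryos)
    expr = spec.resolved_expression()
    state_names = list(expr.index)
    E = expr.to_numpy()
    genes = expr.columns

    cc_idx = None
    if spec.cell_cycle is not None:
        cc_genes, cc_boost, cc_frac = spec.cell_cycle
        cc_idx = genes.get_indexer([g for g in cc_genes if g in genes])

    mat_idx = mat_slope = None
    if spec.maturation:
        mat_idx = genes.get_indexer(list(spec.maturation))
        mat_slope = np.array(list(spec.maturation.values()))

    rows, obs_rows = [], []
    shape = spec.overdispersion_shape
    for ei in range(spec.n_embryos):
        emb = f"emb{ei:03d}"
        p_state = _state_probs(spec, times[ei])
        states = rng.choice(len(state_names), size=n_cells_per[ei], p=p_state)
        depths = np.maximum(rng.poisson(spec.umi_depth, size=n_cells_per[ei]), 1)
        u_t = (times[ei] - t0) / max(t1 - t0, 1e-12)
        if spec.depth_sigma > 0:
            # realistic wide per-cell depth spread (lognormal, mean-preserving)
            mu = np.log(spec.umi_depth) - 0.5 * spec.depth_sigma**2
            depths = np.maximum(
                rng.poisson(rng.lognormal(mu, spec.depth_sigma, size=n_cells_per[ei])), 1
            )
        for ci in range(n_cells_per[ei]):
            p = E[states[ci]].copy()
            if mat_idx is not None:
                # maturation: within-state expression drift along latent time
                p[mat_idx] *= 2.0 ** (mat_slope * u_t)
            cycling = False
            if cc_idx is not None and rng.random() < cc_frac:
                cycling = True
                p[cc_idx] *= cc_boost
            if shape and shape > 0:
                p = p * rng.gamma(shape, 1.0 / shape, size=len(p))
            p /= p.sum()
            rows.append(rng.multinomial(depths[ci], p))
            obs_rows.append(
                {
                    "embryo": emb,
                    "condition": condition,
                    "true_state": state_names[states[ci]],
                    "true_time": times[ei],
                    "is_doublet": False,
                    "is_cycling": cycling,
                }
            )

    X = sp.csr_matrix(np.vstack(rows).astype(np.int64))
    obs = pd.DataFrame(obs_rows, index=[f"cell{i:05d}" for i in range(X.shape[0])])
    var = pd.DataFrame(index=genes)
    var["program"] = [spec.gene_programs.get(g, "background") for g in genes]
    adata = ad.AnnData(X=X, obs=obs, var=var)
    embryos = pd.DataFrame(
        {
            "embryo": [f"emb{i:03d}" for i in range(spec.n_embryos)],
            "true_time": times,
            "n_cells": n_cells_per,
        }
    )
    # nominal collection day: the latent time rounded to quarter days, a crude
    # morphology-style label downstream calibration can lean on
    embryos["nominal_day"] = np.round(times * 4) / 4
    adata.uns["embryos"] = embryos
    if spec.planted_foldchanges:
        adata.uns["planted_foldchanges"] = {
            g: {"start": a, "end": b, "fold": f}
            for g, (a, b, f) in spec.planted_foldchanges.items()
        }
    return SyntheticCohort(counts=adata, embryos=embryos)


@dataclass
class KOSpec:
    """A planted perturbation: gene ablation, frequency shifts, nuisance genes.

    ``target_genes`` maps gene -> residual expression scale (0 = full
    ablation); ``affected_states`` limits the ablation compartment (None =
    everywhere); ``frequency_multipliers`` re-weight state frequencies (then
    renormalized); ``nuisance_genes`` get a condition-specific log2 shift in
    every state, emulating batch-restricted lateral genes.
    """

    target_genes: dict[str, float] = field(default_factory=dict)
    affected_states: list[str] | None = None
    frequency_multipliers: dict[str, float] = field(default_factory=dict)
    nuisance_genes: dict[str, float] = field(default_factory=dict)
    condition: str = "KO"


def generate_perturbation_cohort(base: CohortSpec, ko: KOSpec) -> SyntheticCohort:
    """Simulate a perturbed cohort sharing the base spec's cohort design.

    With an empty ``ko`` the draw is identical to
    ``generate_atlas_cohort(base)`` under the same seed.
    """
    base.validate()
    genes = base.gene_index()
    state_names = {s.name for s in base.states}
    for g in list(ko.target_genes) + list(ko.nuisance_genes):
        if g not in genes:
            raise SpecValidationError(f"ko references unknown gene {g!r}")
    for s in list(ko.frequency_multipliers) + (ko.affected_states or []):
        if s not in state_names:
            raise SpecValidationError(f"ko references unknown state {s!r}")

    spec = copy.deepcopy(base)
    affected = set(ko.affected_states) if ko.affected_states is not None else state_names
    if ko.target_genes or ko.nuisance_genes:
        resolved = base.resolved_expression()
        new_states = []
        for s in spec.states:
            vec = resolved.loc[s.name].to_numpy().copy()
            if s.name in affected:
                for g, scale in ko.target_genes.items():
                    vec[genes.get_loc(g)] *= scale
            for g, shift in ko.nuisance_genes.items():
                vec[genes.get_loc(g)] *= 2.0**shift
            new_states.append(StateSpec(name=s.name, lineage=s.lineage, expression=vec))
        spec.states = new_states
        spec.planted_foldchanges = {}  # already baked into the resolved vectors
    if ko.frequency_multipliers:
        base_curves = dict(base.state_frequency_curves)
        mult = dict(ko.frequency_multipliers)

        def _reweighted(name: str) -> Callable[[float], float]:
            def f(t: float) -> float:
                num = base_curves[name](t) * mult.get(name, 1.0)
                den = sum(base_curves[n](t) * mult.get(n, 1.0) for n in base_curves)
                return num / den

            return f

        spec.state_frequency_curves = {n: _reweighted(n) for n in base_curves}
    cohort = generate_atlas_cohort(spec, condition=ko.condition)
    cohort.counts.uns["ko"] = {
        "target_genes": dict(ko.target_genes),
        "affected_states": sorted(affected),
        "frequency_multipliers": dict(ko.frequency_multipliers),
        "nuisance_genes": dict(ko.nuisance_genes),
    }
    return cohort


def spike_doublets(cohort: SyntheticCohort, rate: float, seed: int = 0) -> SyntheticCohort:
    """Append artificial same-embryo doublets at the given rate.

    Doublets sum the counts of two random cells from one embryo (plate-based
    barcoding makes cross-embryo doublets impossible) and are flagged in the
    truth table. ``rate`` counts doublets relative to the existing cells.
    """
    if not (0.0 <= rate < 0.5):
        raise ValueError("doublet rate must be in [0, 0.5)")
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    adata = cohort.counts
    n = adata.n_obs
    n_dbl = int(round(rate * n))
    embryos = adata.obs["embryo"].to_numpy()
    X = sp.csr_matrix(adata.X)
    new_rows, new_obs = [], []
    eligible = pd.Series(np.arange(n)).groupby(embryos).apply(list)
    eligible = {k: v for k, v in eligible.items() if len(v) >= 2}
    emb_keys = sorted(eligible)
    for d in range(n_dbl):
        emb = emb_keys[rng.integers(len(emb_keys))]
        i, j = rng.choice(eligible[emb], size=2, replace=False)
        new_rows.append(X[i] + X[j])
        new_obs.append(
            {
                "embryo": emb,
                "condition": adata.obs["condition"].iloc[i],
                "true_state": "doublet",
                "true_time": adata.obs["true_time"].iloc[i],
                "is_doublet": True,
                "is_cycling": False,
                "parent_a": adata.obs_names[i],
                "parent_b": adata.obs_names[j],
            }
        )
    Xd = sp.vstack([X] + new_rows, format="csr")
    obs = pd.concat(
        [adata.obs, pd.DataFrame(new_obs, index=[f"dbl{i:05d}" for i in range(n_dbl)])]
    )
    out = ad.AnnData(X=Xd, obs=obs, var=adata.var.copy(), uns=dict(adata.uns))
    return SyntheticCohort(counts=out, embryos=cohort.embryos)


# ---------------------------------------------------------------------- #
# cohort builders
# ---------------------------------------------------------------------- #


def _background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Lognormal housekeeping baseline frequencies (unnormalized)."""
    return np.exp(rng.normal(0.0, 1.0, size=n)) * 1e-3


def epc_cohort_spec(
    n_embryos: int = 12,
    cells_per_embryo: tuple[int, int] = (220, 280),
    n_genes: int = 500,
    umi_depth: float = 3000.0,
    hand1_fold: float = 12.0,
    ascl2_fold: float = 7.0,
    n_intermediates: int = 7,
    seed: int = 0,
    design_seed: int | None = None,
) -> CohortSpec:
    """A continuously bifurcating EPC-like cohort with planted fold-changes.

    ``uncommitted`` progenitors differentiate along two graded branches —
    SpT-Gly-like and TGC-progenitor-like — modelled as ``n_intermediates``
    geometric interpolation steps between the progenitor and each endpoint
    (the continuum the estimators assume, rather than isolated state blobs).
    A Hand1-like transcription factor stays high along the TGC branch and is
    repressed ``hand1_fold``-fold towards the SpT-Gly endpoint; an Ascl2-like
    factor mirrors it with ``ascl2_fold`` towards TGC. Thirty branch-specific
    program genes ramp 10-fold along each branch, carrying the lineage scores.
    """
    rng = np.random.default_rng((seed if design_seed is None else design_seed) + 777)
    n_prog = 30
    names = ["Hand1like", "Ascl2like"]
    names += [f"SptG{i:02d}" for i in range(n_prog)]
    names += [f"TgcG{i:02d}" for i in range(n_prog)]
    n_shared = 10
    names += [f"EpcShared{i:02d}" for i in range(n_shared)]
    n_hk = n_genes - len(names)
    names += [f"Hk{i:03d}" for i in range(n_hk)]

    base = _background(rng, n_genes)
    idx = {g: i for i, g in enumerate(names)}

    unc = base.copy()
    spt = base.copy()
    tgc = base.copy()
    # endpoint declines are baked in directly; the recorded planted folds
    # resolve to the same values (end = start/fold), keeping truth and
    # realized frequencies consistent
    unc[idx["Hand1like"]] = tgc[idx["Hand1like"]] = 5e-3
    spt[idx["Hand1like"]] = 5e-3 / hand1_fold
    unc[idx["Ascl2like"]] = spt[idx["Ascl2like"]] = 5e-3
    tgc[idx["Ascl2like"]] = 5e-3 / ascl2_fold
    for i in range(n_prog):
        s, t = idx[f"SptG{i:02d}"], idx[f"TgcG{i:02d}"]
        unc[s], spt[s], tgc[s] = 8e-4, 8e-3, 4e-4
        unc[t], spt[t], tgc[t] = 8e-4, 4e-4, 8e-3
    for i in range(n_shared):
        sh = idx[f"EpcShared{i:02d}"]
        unc[sh], spt[sh], tgc[sh] = 6e-3, 1e-3, 1e-3
    # balance the housekeeping background so every state vector sums to 1:
    # planted frequency ratios are then realized exactly on the UMI scale
    hk_slice = slice(idx["Hk000"], n_genes)
    for vec in (unc, spt, tgc):
        special = vec[: idx["Hk000"]].sum()
        vec[hk_slice] *= (1.0 - special) / vec[hk_slice].sum()

    states = [
        StateSpec("uncommitted", "epc", expression=unc),
        StateSpec("spt_gly", "epc_spt", expression=spt),
        StateSpec("tgc_prog", "epc_tgc", expression=tgc),
    ]
    step = 1.0 / (n_intermediates + 1)
    for k in range(1, n_intermediates + 1):
        states.append(
            StateSpec(f"spt_i{k}", "epc_spt", interpolate=("uncommitted", "spt_gly", k * step))
        )
        states.append(
            StateSpec(f"tgc_i{k}", "epc_tgc", interpolate=("uncommitted", "tgc_prog", k * step))
        )

    def _weights(t: float) -> dict[str, float]:
        u = np.clip((t - 6.0) / 2.0, 0.0, 1.0)  # 0..1 over the window
        w = {"uncommitted": 0.9 - 0.5 * u, "spt_gly": 0.08 + 0.5 * u, "tgc_prog": 0.08 + 0.5 * u}
        for k in range(1, n_intermediates + 1):
            w[f"spt_i{k}"] = 0.04
            w[f"tgc_i{k}"] = 0.04
        return w

    def _curve(name: str) -> Callable[[float], float]:
        def f(t: float) -> float:
            w = _weights(t)
            return w[name] / sum(w.values())

        return f

    programs = {"Hand1like": "hand1_like", "Ascl2like": "ascl2_like"}
    programs.update({f"SptG{i:02d}": "spt_program" for i in range(n_prog)})
    programs.update({f"TgcG{i:02d}": "tgc_program" for i in range(n_prog)})
    programs.update({f"EpcShared{i:02d}": "epc_shared" for i in range(n_shared)})

    return CohortSpec(
        n_embryos=n_embryos,
        cells_per_embryo=cells_per_embryo,
        n_genes=n_genes,
        states=states,
        state_frequency_curves={s.name: _curve(s.name) for s in states},
        latent_time_range=(6.0, 8.0),
        planted_foldchanges={
            "Hand1like": ("uncommitted", "spt_gly", hand1_fold),
            "Ascl2like": ("uncommitted", "tgc_prog", ascl2_fold),
        },
        umi_depth=umi_depth,
        gene_names=names,
        gene_programs=programs,
        seed=seed,
    )


def default_atlas_spec(
    n_embryos: int = 30,
    cells_per_embryo: tuple[int, int] = (180, 260),
    n_genes: int = 400,
    umi_depth: float = 1500.0,
    rare_fraction: float = 0.015,
    seed: int = 0,
    design_seed: int | None = None,
) -> CohortSpec:
    """A whole-atlas stand-in: two branching lineages plus a rare precursor.

    Nine states drift smoothly over latent time 5.5-9.5: an early progenitor
    declines while two three-step lineages (an EPC-like bifurcation and a
    chorion-like switch) mature, alongside a rare precursor held at
    ``rare_fraction``. Each state carries ~20 markers elevated over a shared
    lognormal background, and the gene universe includes the S-/M-phase
    cell-cycle symbols with a planted cycling-cell program.
    """
    rng = np.random.default_rng((seed if design_seed is None else design_seed) + 555)
    cc_genes = list(S_PHASE_GENES) + list(M_PHASE_GENES)
    mat_up = [f"MatUp{i:02d}" for i in range(20)]
    mat_dn = [f"MatDn{i:02d}" for i in range(20)]
    state_list = [
        ("progenitor", "root"),
        ("epc_a1", "epc"),
        ("epc_a2", "epc"),
        ("epc_a3", "epc"),
        ("chor_b1", "chorion"),
        ("chor_b2", "chorion"),
        ("chor_b3", "chorion"),
        ("rare_precursor", "pgc"),
        ("endoderm", "endoderm"),
    ]
    n_marker = 20
    names = list(cc_genes) + mat_up + mat_dn
    marker_idx: dict[str, list[int]] = {}
    for sname, _ in state_list:
        start = len(names)
        names += [f"{sname}_mk{i:02d}" for i in range(n_marker)]
        marker_idx[sname] = list(range(start, start + n_marker))
    n_hk = n_genes - len(names)
    if n_hk < 0:
        raise SpecValidationError("n_genes too small for the atlas gene layout")
    names += [f"Hk{i:03d}" for i in range(n_hk)]

    base = _background(rng, n_genes)
    base[: len(cc_genes)] = 5e-4  # cell-cycle baseline, boosted in cycling cells
    base[len(cc_genes) : len(cc_genes) + 40] = 1.5e-3  # maturation gene baseline

    states = []
    for sname, lineage in state_list:
        vec = base.copy()
        vec[marker_idx[sname]] *= 8.0
        # lineage continuity: each step keeps a half-strength echo of the
        # previous state's markers so branches form graded trajectories
        order = [n for n, _ in state_list]
        pos = order.index(sname)
        if lineage in ("epc", "chorion") and not sname.endswith("1"):
            vec[marker_idx[order[pos - 1]]] *= 3.0
        states.append(StateSpec(sname, lineage, expression=vec))

    def _weights(t: float) -> dict[str, float]:
        u = (t - 5.5) / 4.0  # 0..1
        w = {
            "progenitor": max(1.0 - 1.1 * u, 0.05),
            "epc_a1": 0.25 + 0.1 * u,
            "epc_a2": 0.05 + 0.45 * u,
            "epc_a3": 0.02 + 0.55 * u,
            "chor_b1": 0.25 - 0.15 * u,
            "chor_b2": 0.05 + 0.35 * u,
            "chor_b3": 0.02 + 0.5 * u,
            "endoderm": 0.15 + 0.1 * u,
        }
        tot = sum(w.values())
        scale = (1.0 - rare_fraction) / tot
        out = {k: v * scale for k, v in w.items()}
        out["rare_precursor"] = rare_fraction
        return out

    def _curve(name: str) -> Callable[[float], float]:
        def f(t: float) -> float:
            return _weights(t)[name]

        return f

    programs = {g: "cell_cycle" for g in cc_genes}
    programs.update({g: "maturation_up" for g in mat_up})
    programs.update({g: "maturation_down" for g in mat_dn})
    for sname, _ in state_list:
        for i in marker_idx[sname]:
            programs[names[i]] = f"{sname}_markers"

    return CohortSpec(
        n_embryos=n_embryos,
        cells_per_embryo=cells_per_embryo,
        n_genes=n_genes,
        states=states,
        state_frequency_curves={s.name: _curve(s.name) for s in states},
        latent_time_range=(5.5, 9.5),
        umi_depth=umi_depth,
        gene_names=names,
        gene_programs=programs,
        cell_cycle=(cc_genes, 6.0, 0.35),
        maturation={**{g: 2.0 for g in mat_up}, **{g: -2.0 for g in mat_dn}},
        seed=seed,
    )
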