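"""Pipeline orchestration: configuration, staged execution, output manifest.

A pipeline config is a YAML/JSON mapping with one block per stage
(``cohort``, ``qc``, ``atlas``, ``chrono``, ``kinetics``, ``perturb``) plus a
global ``seed`` and ``outdir``. Stages run in dependency order
(simulate -> qc -> atlas -> chrono -> kinetics -> perturb), communicate only
through files, and append to a manifest (path, sha256, producing stage) so a
re-run with identical config reproduces identical checksums. All randomness
derives from the root seed through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import atlas, chrono, kinetics, qc, syndata
from .io import read_cohort, write_cohort

logger = logging.getLogger("embryochrono")

STAGES = ["simulate", "qc", "atlas", "chrono", "kinetics", "perturb"]
_KNOWN_KEYS = {"seed", "outdir", "cohort", "qc", "atlas", "chrono", "kinetics", "perturb"}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    cohort: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    atlas: dict = field(default_factory=dict)
    chrono: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    perturb: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def stage_seed(self, stage: str) -> int:
        h = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode()) % (2**31)])
        return int(h.generate_state(1)[0] % (2**31))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _record(manifest: list, stage: str, *paths: str) -> None:
    for p in paths:
        if os.path.isdir(p):
            for f in sorted(os.listdir(p)):
                manifest.append(
                    {"file": os.path.join(p, f), "sha256": _sha256(os.path.join(p, f)), "stage": stage}
                )
        else:
            manifest.append({"file": p, "sha256": _sha256(p), "stage": stage})


def _build_spec(cfg: PipelineConfig) -> syndata.CohortSpec:
    block = dict(cfg.cohort)
    kind = block.pop("kind", "atlas")
    block.setdefault("seed", cfg.stage_seed("simulate"))
    if "cells_per_embryo" in block:
        block["cells_per_embryo"] = tuple(block["cells_per_embryo"])
    if kind == "epc":
        return syndata.epc_cohort_spec(**block)
    if kind == "atlas":
        return syndata.default_atlas_spec(**block)
    raise ConfigError(f"unknown cohort kind {kind!r}")


def run_pipeline(config: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    Missing upstream outputs raise an error naming the stage to run first.
    """
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest: list[dict] = []
    paths = {
        "cohort": os.path.join(out, "cohort"),
        "filtered": os.path.join(out, "filtered"),
        "qc_report": os.path.join(out, "qc_report.tsv"),
        "metacells": os.path.join(out, "metacells.tsv"),
        "e": os.path.join(out, "metacell_e.tsv"),
        "celltypes": os.path.join(out, "metacell_types.tsv"),
        "features": os.path.join(out, "feature_genes.tsv"),
        "timeline": os.path.join(out, "timeline.tsv"),
        "cc_scores": os.path.join(out, "cell_cycle_scores.tsv"),
        "prolif": os.path.join(out, "proliferation_rates.tsv"),
        "de": os.path.join(out, "de_ko_vs_wt.tsv"),
        "freq": os.path.join(out, "celltype_frequencies.tsv"),
    }

    def _require(path: str, producer: str) -> None:
        if not os.path.exists(path):
            raise ConfigError(f"missing {path}; run stage {producer!r} first")

    for stage in stages:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            spec = _build_spec(config)
            cohort = syndata.generate_atlas_cohort(spec)
            rate = config.cohort.get("doublet_rate", spec.doublet_rate)
            if rate:
                cohort = syndata.spike_doublets(cohort, rate, seed=config.stage_seed("doublets"))
            write_cohort(cohort.counts, paths["cohort"])
            ko_block = config.perturb.get("ko")
            if ko_block:
                ko = syndata.generate_perturbation_cohort(spec, syndata.KOSpec(**ko_block))
                write_cohort(ko.counts, os.path.join(out, "cohort_ko"))
                _record(manifest, stage, os.path.join(out, "cohort_ko"))
            _record(manifest, stage, paths["cohort"])
        elif stage == "qc":
            _require(paths["cohort"], "simulate")
            adata = read_cohort(paths["cohort"])
            params = qc.QCParams(**config.qc.get("params", {}))
            kept, report = qc.filter_cells(adata, params)
            if config.qc.get("doublets", False):
                report["pANN"] = qc.doublet_scores(adata, params, seed=config.stage_seed("qc"))
                keep = report.loc[kept.obs_names, "pANN"] <= params.pANN_threshold
                kept = kept[keep.to_numpy()].copy()
            report.to_csv(paths["qc_report"], sep="\t")
            write_cohort(kept, paths["filtered"])
            _record(manifest, stage, paths["qc_report"], paths["filtered"])
        elif stage == "atlas":
            _require(paths["filtered"], "qc")
            adata = read_cohort(paths["filtered"])
            feats, stats = atlas.select_feature_genes(
                adata,
                atlas.FeatureSelectionParams(**config.atlas.get("features", {})),
                lateral_markers={
                    "s_phase": list(kinetics.S_PHASE_GENES),
                    "m_phase": list(kinetics.M_PHASE_GENES),
                },
                seed=config.stage_seed("atlas"),
            )
            model = atlas.build_metacells(
                adata, feats, seed=config.stage_seed("atlas"), **config.atlas.get("metacells", {})
            )
            if "true_state" in adata.obs:
                model.annotate(adata.obs["true_state"])
            pd.Series(feats, name="gene").to_csv(paths["features"], sep="\t", index=False)
            model.partition.rename("metacell").to_csv(paths["metacells"], sep="\t")
            model.e.to_csv(paths["e"], sep="\t")
            model.celltype.rename("celltype").to_csv(paths["celltypes"], sep="\t")
            _record(manifest, stage, paths["features"], paths["metacells"], paths["e"], paths["celltypes"])
        elif stage == "chrono":
            _require(paths["metacells"], "atlas")
            adata = read_cohort(paths["filtered"])
            model = _load_model(paths, adata)
            embryos = adata.uns["embryos"]
            nominal = embryos.set_index("embryo")["nominal_day"]
            timeline = chrono.make_timeline(
                model,
                adata.obs["embryo"],
                nominal,
                n_bins=config.chrono.get("n_bins", 16),
                seed=config.stage_seed("chrono"),
            )
            tl = pd.DataFrame(
                {"rank": timeline.rank, "Et": timeline.Et, "age_bin": timeline.age_bin}
            )
            tl.index.name = "embryo"
            tl.to_csv(paths["timeline"], sep="\t")
            _record(manifest, stage, paths["timeline"])
        elif stage == "kinetics":
            _require(paths["filtered"], "qc")
            adata = read_cohort(paths["filtered"])
            scores = kinetics.cell_cycle_scores(adata)
            scores.to_csv(paths["cc_scores"], sep="\t")
            model = _load_model(paths, adata) if os.path.exists(paths["metacells"]) else None
            outputs = [paths["cc_scores"]]
            if model is not None:
                mc_score = (scores.sum(axis=1)).groupby(model.partition).mean()
                chrono.proliferation_rate(mc_score).to_csv(paths["prolif"], sep="\t")
                outputs.append(paths["prolif"])
            _record(manifest, stage, *outputs)
        elif stage == "perturb":
            ko_dir = os.path.join(out, "cohort_ko")
            _require(ko_dir, "simulate")
            _require(paths["filtered"], "qc")
            wt = read_cohort(paths["filtered"])
            ko = read_cohort(ko_dir)
            from .perturb import chisq_de, compare_celltype_frequencies

            g_wt = pd.Series(
                np.asarray(wt.X.sum(axis=0)).ravel(), index=wt.var_names
            )
            g_ko = pd.Series(
                np.asarray(ko.X.sum(axis=0)).ravel(), index=ko.var_names
            )
            de = chisq_de(g_wt, g_ko)
            de.to_csv(paths["de"], sep="\t")
            comp_wt = _composition(wt)
            comp_ko = _composition(ko)
            freq = compare_celltype_frequencies(comp_ko, comp_wt, mode="per_embryo")
            freq.to_csv(paths["freq"], sep="\t")
            _record(manifest, stage, paths["de"], paths["freq"])

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"seed": config.seed, "stages": stages, "files": manifest}, fh, indent=1)
    return {"manifest": manifest, "manifest_path": manifest_path}


def _load_model(paths: dict, adata) -> atlas.MetacellModel:
    part = pd.read_csv(paths["metacells"], sep="\t", index_col=0)["metacell"]
    part = part.reindex(adata.obs_names)
    e, le, lf = atlas.metacell_expression(part, adata)
    model = atlas.MetacellModel(partition=part, e=e, le=le, lf=lf)
    if os.path.exists(paths["celltypes"]):
        ct = pd.read_csv(paths["celltypes"], sep="\t", index_col=0)["celltype"]
        model.celltype = ct
    return model


def _composition(adata) -> pd.DataFrame:
    comp = (
        pd.DataFrame({"embryo": adata.obs["embryo"], "celltype": adata.obs["true_state"]})
        .groupby(["embryo", "celltype"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    return comp.div(comp.sum(axis=1), axis=0)
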