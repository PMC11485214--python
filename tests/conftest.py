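"""Shared fixtures: small synthetic cohorts and cached pipeline runs.

Heavy end-to-end pipeline results are cached per seed at session scope so
unit tests and the acceptance tests reuse the same computations.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from embryochrono import pipelines, syndata


@functools.lru_cache(maxsize=None)
def epc_result(seed: int) -> dict:
    return pipelines.epc_fold_recovery(seed=seed)


@functools.lru_cache(maxsize=None)
def ordering_result(seed: int) -> dict:
    return pipelines.ordering_recovery(seed=seed)


@functools.lru_cache(maxsize=None)
def holdout_result(seed: int) -> dict:
    return pipelines.held_out_annotation(seed=seed)


@functools.lru_cache(maxsize=None)
def ko_result(seed: int) -> dict:
    return pipelines.ko_recovery(seed=seed)


@pytest.fixture(scope="session")
def epc_seed1() -> dict:
    return epc_result(1)


@pytest.fixture(scope="session")
def ko_seed1() -> dict:
    return ko_result(1)


@pytest.fixture(scope="session")
def holdout_seed1() -> dict:
    return holdout_result(1)


@pytest.fixture(scope="session")
def small_cohort() -> syndata.SyntheticCohort:
    """A small multi-state cohort for unit tests (~500 cells)."""
    spec = syndata.default_atlas_spec(
        n_embryos=6, cells_per_embryo=(70, 100), seed=11
    )
    return syndata.generate_atlas_cohort(spec)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    model, feats = pipelines.build_annotated_model(small_cohort, seed=11)
    return model, feats


def make_flat_spec(
    n_genes: int = 10, depth: float = 1000.0, n_cells: int = 200, seed: int = 0
) -> syndata.CohortSpec:
    """One state, uniform expression: the simplest sampling test bed."""
    expr = np.full(n_genes, 1.0 / n_genes)
    return syndata.CohortSpec(
        n_embryos=2,
        cells_per_embryo=(n_cells // 2, n_cells // 2),
        n_genes=n_genes,
        states=[syndata.StateSpec("flat", expression=expr)],
        state_frequency_curves={"flat": lambda t: 1.0},
        umi_depth=depth,
        overdispersion_shape=0.0,
        seed=seed,
    )
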