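"""Simulate the study cohorts: a WT atlas cohort and an EPC lineage cohort.

Writes MTX+TSV cohort directories under results/cohorts/ and a summary of
the planted ground truth.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from embryochrono import io, syndata  # noqa: E402

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "cohorts")
SEED = 1


def main() -> None:
    atlas_spec = syndata.default_atlas_spec(seed=SEED)
    atlas_cohort = syndata.generate_atlas_cohort(atlas_spec)
    io.write_cohort(atlas_cohort.counts, os.path.join(OUT, "atlas"))
    print(
        f"atlas cohort: {atlas_cohort.counts.n_obs} cells, "
        f"{atlas_cohort.counts.n_vars} genes, "
        f"{atlas_spec.n_embryos} embryos over "
        f"E_t {atlas_spec.latent_time_range[0]}-{atlas_spec.latent_time_range[1]}"
    )
    print(atlas_cohort.counts.obs["true_state"].value_counts().to_string())

    epc_spec = syndata.epc_cohort_spec(seed=SEED)
    epc_cohort = syndata.generate_atlas_cohort(epc_spec)
    io.write_cohort(epc_cohort.counts, os.path.join(OUT, "epc"))
    planted = epc_cohort.counts.uns["planted_foldchanges"]
    print(
        f"\nEPC cohort: {epc_cohort.counts.n_obs} cells; planted folds: "
        + ", ".join(f"{g} {v['fold']:g}x ({v['start']}->{v['end']})" for g, v in planted.items())
    )


if __name__ == "__main__":
    main()
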