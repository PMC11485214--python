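"""Build the metacell atlas: feature genes, partition, expression model.

Reads results/cohorts/atlas and writes the feature list, metacell
assignment, e/le matrices and metacell type annotation.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd  # noqa: E402

from embryochrono import atlas, io, kinetics  # noqa: E402

BASE = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 1


def main() -> None:
    adata = io.read_cohort(os.path.join(BASE, "cohorts", "atlas"))
    lateral = {
        "s_phase": list(kinetics.S_PHASE_GENES),
        "m_phase": list(kinetics.M_PHASE_GENES),
    }
    feats, stats = atlas.select_feature_genes(adata, lateral_markers=lateral, seed=SEED)
    n_cand = int(stats["candidate"].sum())
    print(f"feature selection: {n_cand} candidates -> {len(feats)} features "
          f"after removing cell-cycle-enriched clusters")

    model = atlas.build_metacells(adata, feats, seed=SEED)
    model.annotate(adata.obs["true_state"])
    sizes = model.sizes()
    print(f"{len(model.metacells)} metacells, sizes {sizes.min()}-{sizes.max()} "
          f"(median {int(sizes.median())})")

    purity = []
    for m in model.metacells:
        cells = model.partition.index[model.partition == m]
        purity.append(adata.obs.loc[cells, "true_state"].value_counts(normalize=True).iloc[0])
    print(f"majority-state purity: median {pd.Series(purity).median():.2f}")

    pd.Series(feats, name="gene").to_csv(os.path.join(BASE, "feature_genes.tsv"), sep="\t", index=False)
    model.partition.rename("metacell").to_csv(os.path.join(BASE, "metacell_assignment.tsv"), sep="\t")
    model.e.to_csv(os.path.join(BASE, "metacell_e.tsv"), sep="\t")
    model.celltype.rename("celltype").to_csv(os.path.join(BASE, "metacell_types.tsv"), sep="\t")


if __name__ == "__main__":
    main()
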