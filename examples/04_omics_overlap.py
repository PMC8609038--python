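"""Differential-set overlap and sample clustering on a synthetic LFQ matrix.

Two treatments get planted altered-feature sets sharing 50% of their union
(Venn overlap). After log2 + median normalization, per-feature Welch/BH
significance and the |log2FC| >= 0.5 cutoff define each treatment's altered
set; the overlap percentage and the clustering of per-replicate log2FC
profiles should both recover the planted structure.
"""

from aggrescreen import omicsets as om
from aggrescreen.synthdata import (
    OmicsSimConfig,
    planted_sets_with_overlap,
    simulate_omics,
)

sets = planted_sets_with_overlap(("drugA", "drugB"), n_features=2000,
                                 set_size=200, overlap=0.5, seed=5)
matrix, truth = simulate_omics(
    OmicsSimConfig(n_features=2000, planted_sets=sets,
                   effect_sd=3.0, noise_sd=0.1, seed=5)
)

norm = om.normalize_lfq(matrix)
print(f"per-sample medians after normalization (should all be 0): "
      f"{norm.values.median().abs().max():.1e}")

altered = {}
for treatment in ("drugA", "drugB"):
    flags = om.welch_flags(norm, treatment, "control")
    altered[treatment] = om.altered_set(norm, treatment, "control", flags=flags)
    planted = truth.planted_ids(treatment)
    print(f"{treatment}: {len(altered[treatment])} altered features "
          f"(planted {len(planted)}; exact match: "
          f"{altered[treatment].features == planted})")

overlap = om.overlap_percent(altered["drugA"], altered["drugB"])
print(f"Venn overlap of the two altered sets: {overlap:.1f}% (planted 50%)")

dendro = om.cluster_samples(om.log2fc_profiles(matrix, "control"))
print("clusters at k=2 (replicates should group by treatment):", dendro.cut(2))
print("dendrogram:", dendro.newick())
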