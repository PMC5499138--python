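"""Diversity indices, MDS, and marker status changes between two epochs.

Simulates founders and a drifted descendant group, then computes the
Shannon index and heterozygosity per group, embeds the samples with
classical MDS on identity-by-state distances, and classifies each
marker's polymorphism-status change (allele swap, polymorphic->monomorphic,
monomorphic->polymorphic) with positional clustering of the changed SNPs.
"""

import numpy as np

from rcgs import (
    allele_frequencies,
    bulk_intermate,
    classical_mds,
    classify_marker_status,
    cluster_changed_snps,
    diversity_report,
    frequency_shift_summary,
    half_diallel,
    ibs_distance,
    simulate_founders,
    simulate_map,
)
from rcgs.genome import GenotypeTable

rng = np.random.default_rng(11)
gmap = simulate_map(10, 150, seed=1)
panel = simulate_founders(gmap, 18, seed=2)

# a small drifted population: intermate a handful of founders for 3 generations
pop = half_diallel(panel.population.subset(np.arange(6)), 2, rng)
for gen in range(3):
    pop = bulk_intermate(pop, 30, rng, cycle=f"G{gen}")

combined = GenotypeTable(
    panel.genotypes.samples + pop.ids,
    gmap,
    np.vstack([panel.genotypes.dosage, pop.dosages()]),
)
groups = {"founders": panel.genotypes.samples, "drifted": pop.ids}
print(diversity_report(combined, groups).to_string(index=False))

coords, evals = classical_mds(ibs_distance(combined), dims=3)
print(f"\nMDS: top-3 eigenvalues {np.round(evals[:3], 3)}")
print("founders and the drifted group separate along dimension 1:")
print(coords.groupby(coords.index.isin(pop.ids))["dim1"].mean().rename(index={False: "founders", True: "drifted"}))

e1 = allele_frequencies(combined, groups["founders"], label="founders")
e2 = allele_frequencies(combined, groups["drifted"], label="drifted")
report = classify_marker_status(e1, e2)
print("\nstatus-change counts:")
print(report.counts().to_string())
clusters = cluster_changed_snps(report, gmap, max_gap_bp=1000, min_size=3)
print(f"positional clusters (>=3 SNPs, <1000 bp gaps): {len(clusters)}")
print("shift summary:", frequency_shift_summary(e1, e2))
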