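"""Pan/core-genome rarefaction, Heap's law and core-region delimitation.

Uses the simulator's ground-truth family labels as the orthology source;
with real data the same calls take the BBH-derived family set.
"""

import pandas as pd

from linsynt import (
    EvolutionParams,
    classify_architecture,
    core_region,
    evolve_tree,
    generate_ancestor,
    heaps_fit,
    random_coalescent_tree,
    rarefaction,
)
from linsynt.orthology import FamilySet

params = EvolutionParams(seed=3)
truth = evolve_tree(
    generate_ancestor(params), random_coalescent_tree(12, seed=3, height=0.25), params
)
ids = sorted(truth.leaves)
fam_sets = {g: {x.family_id for x in truth.leaves[g]} for g in ids}
fams_all = sorted(set.union(*fam_sets.values()))
presence = pd.DataFrame(
    [[int(f in fam_sets[g]) for g in ids] for f in fams_all], index=fams_all, columns=ids
)
families = FamilySet(presence, {f: [] for f in fams_all}, set())

print(f"{len(ids)} genomes: pan-genome {families.pan_size} families, "
      f"core-genome {len(families.core)} families")

rar = rarefaction(families, iterations=100, seed=3)
med = rar.groupby("n").median()
print("median core / pan by subset size:")
for n in (2, 4, 8, len(ids)):
    print(f"  n={n:2d}: core {med.core_size[n]:.0f}  pan {med.pan_size[n]:.0f}")
kappa, gamma = heaps_fit(med.pan_size)
print(f"Heap's law pan(n) ~ {kappa:.0f} * n^{gamma:.3f} "
      f"(gamma > 0: still-open pan-genome)")

ref = truth.leaves[ids[0]]
core_ids = {g.gene_id for g in ref if g.family_id in set(families.core)}
region = core_region(ref, core_ids)
print(f"{ref.genome_id}: core-region ranks {region.start_rank}-{region.end_rank} "
      f"({region.start_bp:,}-{region.end_bp:,} bp), arms "
      f"{region.left_arm_bp:,} / {region.right_arm_bp:,} bp "
      f"-> {classify_architecture(region)} architecture")
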