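"""Six-portion OR trends and early-divergence slopes.

Splits the reference chromosome into six equal-gene portions, computes OR
against every other genome, and fits per-portion trends against
cophenetic distance; the early slope (distance 0-0.1) contrasts the
fast-eroding terminal portions with the conserved centre.
"""

import pandas as pd

from linsynt import (
    EvolutionParams,
    evolve_tree,
    fit_trend,
    generate_ancestor,
    portion_index_scan,
    random_coalescent_tree,
    split_portions,
    truth_orthology_map,
)

params = EvolutionParams(seed=0)
tree = random_coalescent_tree(20, seed=0, height=0.25)
truth = evolve_tree(generate_ancestor(params), tree, params)
ids = sorted(truth.leaves)

tables = []
for ref_id in ids:
    ref = truth.leaves[ref_id]
    others = [truth.leaves[g] for g in ids if g != ref_id]
    maps = {g: truth_orthology_map(ref, truth.leaves[g]) for g in ids if g != ref_id}
    tables.append(
        portion_index_scan(ref, others, maps, split_portions(ref, 6), "OR", tree=tree)
    )
tbl = pd.concat(tables, ignore_index=True)

print("portion  mean OR   early slope (distance 0-0.1)")
for p in range(1, 7):
    sub = tbl[tbl.portion == p]
    fit = fit_trend(sub, degree=3)
    tag = "terminal" if p in (1, 6) else "central"
    print(f"   {p}      {sub['value'].mean():.3f}     {fit.alpha_early:+.2f}   ({tag})")
print("terminal portions decline faster from the origin: arms evolve fastest.")
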