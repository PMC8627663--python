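import numpy as np
import pytest

from linsynt import (
    EvolutionParams,
    GeneRecord,
    LinearChromosome,
    OrthologyMap,
    evolve_tree,
    generate_ancestor,
    random_coalescent_tree,
)


def make_chrom(genome_id, genes, gene_len=900, spacer=100, tir=0):
    """Build a chromosome from [(gene_id, strand)] or [(gene_id, strand, family)]."""
    records = []
    for i, g in enumerate(genes):
        gid, strand = g[0], g[1]
        fam = g[2] if len(g) > 2 else gid
        start = tir + spacer + i * (gene_len + spacer) + 1
        records.append(
            GeneRecord(gid, genome_id, i, start, start + gene_len - 1, strand, family_id=fam)
        )
    length = 2 * tir + (len(genes) + 1) * spacer + len(genes) * gene_len
    return LinearChromosome(genome_id, records, length_bp=length, tir_length_bp=tir)


def make_map(genome_a, genome_b, pairs):
    m = OrthologyMap(genome_a, genome_b)
    for a, b in pairs:
        m.add(a, b)
    return m


@pytest.fixture
def fig2_toy():
    """Eight-gene reference with six orthologues, one of them isolated.

    The compared genome keeps the adjacencies (r1,r2), (r2,r3) and (r7,r8);
    r5 has an orthologue but both its neighbours do not.
    """
    ref = make_chrom("refA", [(f"r{i}", "+") for i in range(1, 9)])
    other = make_chrom("cmpB", [(f"b{i}", "+") for i in (1, 2, 3, 5, 7, 8)])
    omap = make_map("refA", "cmpB", [(f"r{i}", f"b{i}") for i in (1, 2, 3, 5, 7, 8)])
    return ref, other, omap


@pytest.fixture(scope="session")
def small_truth():
    """Eight-leaf simulation with moderate rates, shared across tests."""
    params = EvolutionParams(
        n_core=60, n_accessory_init=60, seed=7, rate_gain=0.6, rate_loss=0.6,
        rate_inversion=0.08, tir_length_bp=500,
    )
    tree = random_coalescent_tree(8, seed=11, height=0.25)
    ancestor = generate_ancestor(params)
    return evolve_tree(ancestor, tree, params)


def presence_from_truth(truth):
    """Family presence/absence matrix from simulator ground-truth labels."""
    import pandas as pd

    from linsynt.orthology import FamilySet

    ids = sorted(truth.leaves)
    fam_sets = {g: {x.family_id for x in truth.leaves[g]} for g in ids}
    all_fams = sorted(set.union(*fam_sets.values()))
    mat = pd.DataFrame(
        [[int(f in fam_sets[g]) for g in ids] for f in all_fams],
        index=all_fams,
        columns=ids,
    )
    return FamilySet(mat, {f: [] for f in all_fams}, set())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
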