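import itertools

import numpy as np
import pandas as pd
import pytest

from linsynt import (
    SimilarityHit,
    all_vs_all_protein_hits,
    bbh_orthologs,
    build_families,
    classify_architecture,
    core_region,
    emit_sequences,
    heaps_fit,
    rarefaction,
    truth_orthology_map,
)
from linsynt.pangenome import CoreRegion

from _oracles import minimal_core_interval
from conftest import make_chrom, make_map


def hit(q, s, identity=95.0, cov=99.0, evalue=1e-80, bitscore=500.0):
    return SimilarityHit(q, s, identity, 300, evalue, bitscore, q_cov=cov, s_cov=cov)


class TestBBH:
    def test_reciprocal_best_pair_mapped(self):
        m = bbh_orthologs([hit("x", "y")], [hit("y", "x")])
        assert m.pairs() == [("x", "y")]

    def test_identity_below_threshold_rejected(self):
        m = bbh_orthologs([hit("x", "y", identity=39.0)], [hit("y", "x", identity=39.0)])
        assert len(m) == 0

    def test_non_reciprocal_unmapped(self):
        # x's best is y but y's best is z
        m = bbh_orthologs(
            [hit("x", "y")],
            [hit("y", "z", bitscore=900.0), hit("y", "x", bitscore=500.0)],
        )
        assert len(m) == 0

    def test_evalue_gate_is_strict(self):
        m = bbh_orthologs([hit("x", "y", evalue=1e-10)], [hit("y", "x", evalue=1e-10)])
        assert len(m) == 0

    def test_order_independence_of_input_hits(self):
        ab = [hit("x1", "y1"), hit("x1", "y2", bitscore=499.0), hit("x2", "y2")]
        ba = [hit("y1", "x1"), hit("y2", "x2"), hit("y2", "x1", bitscore=499.0)]
        expected = bbh_orthologs(ab, ba).pairs()
        for pab in itertools.permutations(ab):
            for pba in itertools.permutations(ba):
                m = bbh_orthologs(list(pab), list(pba))
                assert sorted(m.pairs()) == sorted(expected)
                # injectivity
                assert len(set(m.a_to_b.values())) == len(m)

    def test_truth_recovery_on_identical_sequences(self):
        from linsynt import (
            EvolutionParams,
            evolve_tree,
            generate_ancestor,
            random_coalescent_tree,
        )

        p = EvolutionParams(
            n_core=12, n_accessory_init=12, substitution_rate=0.0, seed=3,
            rate_gain=0.3, rate_loss=0.3, rate_inversion=0.05,
        )
        truth = evolve_tree(generate_ancestor(p), random_coalescent_tree(2, seed=8), p)
        _, prots = emit_sequences(truth)
        a, b = sorted(truth.leaves)
        m = bbh_orthologs(
            all_vs_all_protein_hits(prots[a], prots[b]),
            all_vs_all_protein_hits(prots[b], prots[a]),
            genome_a=a, genome_b=b,
        )
        expected = truth_orthology_map(truth.leaves[a], truth.leaves[b])
        assert sorted(m.pairs()) == sorted(expected.pairs())


class TestFamilies:
    def test_clique_gives_single_full_family(self):
        maps = [
            make_map("A", "B", [("g", "g")]),
            make_map("A", "C", [("g", "g")]),
            make_map("B", "C", [("g", "g")]),
        ]
        fams = build_families(maps, ["A", "B", "C"])
        assert fams.pan_size == 1
        assert fams.presence.iloc[0].tolist() == [1, 1, 1]

    def test_private_gene_is_singleton(self):
        fams = build_families(
            [make_map("A", "B", [("shared", "shared")])],
            ["A", "B", "C"],
            gene_lists={"A": ["shared", "only_a"], "B": ["shared"], "C": []},
        )
        assert fams.pan_size == 2
        rows = fams.presence.sum(axis=1)
        assert sorted(rows.tolist()) == [1, 2]

    def test_transitivity_conflict_flagged(self):
        maps = [
            make_map("A", "B", [("a1", "b1")]),
            make_map("B", "C", [("b1", "c1")]),
            make_map("C", "A", [("c1", "a2")]),
        ]
        fams = build_families(maps, ["A", "B", "C"])
        assert fams.pan_size == 1
        assert len(fams.inconsistent) == 1


from conftest import presence_from_truth  # noqa: E402


class TestRarefaction:
    def test_identical_genomes_flat_curves(self):
        pres = pd.DataFrame(np.ones((40, 4), dtype=int), columns=list("ABCD"))
        from linsynt.orthology import FamilySet

        fams = FamilySet(pres, {}, set())
        rar = rarefaction(fams, iterations=10, seed=1)
        assert (rar.core_size == 40).all() and (rar.pan_size == 40).all()

    def test_full_set_equals_global_core_and_pan(self, small_truth):
        fams = presence_from_truth(small_truth)
        n = fams.presence.shape[1]
        rar = rarefaction(fams, n_range=[n], iterations=5, seed=2)
        assert (rar.core_size == len(fams.core)).all()
        assert (rar.pan_size == fams.pan_size).all()

    def test_median_pan_grows_and_core_shrinks(self, small_truth):
        fams = presence_from_truth(small_truth)
        rar = rarefaction(fams, iterations=50, seed=3)
        med = rar.groupby("n").median()
        assert (np.diff(med.pan_size) >= 0).all() and med.pan_size.iloc[-1] > med.pan_size.iloc[0]
        assert (np.diff(med.core_size) <= 0).all()


class TestHeaps:
    def test_exact_power_law_recovered(self):
        n = np.arange(2, 30)
        kappa, gamma = heaps_fit(pd.Series(200.0 * n**0.6, index=n))
        assert kappa == pytest.approx(200.0, abs=1e-6)
        assert gamma == pytest.approx(0.6, abs=1e-6)

    def test_constant_pan_is_closed(self):
        n = np.arange(2, 20)
        _, gamma = heaps_fit(pd.Series(500.0, index=n))
        assert gamma == pytest.approx(0.0, abs=1e-12)

    def test_recovery_under_multiplicative_noise(self, rng):
        n = np.arange(2, 51)
        pan = 150.0 * n**0.5 * np.exp(rng.normal(0, 0.05, size=len(n)))
        _, gamma = heaps_fit(pd.Series(pan, index=n))
        assert gamma == pytest.approx(0.5, abs=0.05)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            heaps_fit(pd.Series([10.0, 20.0], index=[2, 3]))
        with pytest.raises(ValueError):
            heaps_fit(pd.Series([10.0, 0.0, 20.0], index=[2, 3, 4]))


class TestCoreRegion:
    def chrom_with_core(self, n, core_ranks):
        genes = [(f"g{i}", "+") for i in range(n)]
        chrom = make_chrom("G", genes)
        return chrom, {f"g{r}" for r in core_ranks}

    def test_clustered_core_drops_one_endpoint(self):
        chrom, core = self.chrom_with_core(100, range(10, 30))
        reg = core_region(chrom, core)
        assert reg.n_core_contained == 19
        assert (reg.end_rank - reg.start_rank + 1) == 19  # all core contiguous

    def test_fraction_one_with_all_core_spans_everything(self):
        chrom, core = self.chrom_with_core(50, range(50))
        reg = core_region(chrom, core, fraction=1.0)
        assert (reg.start_rank, reg.end_rank) == (0, 49)
        assert reg.left_arm_bp == chrom.genes[0].start - 1
        assert classify_architecture(reg) == "typical"

    def test_outlier_core_gene_dropped_for_minimal_span(self):
        ranks = [0] + list(range(50, 68)) + [99]
        chrom, core = self.chrom_with_core(100, ranks)
        reg = core_region(chrom, core)
        oracle = minimal_core_interval(ranks, 100)
        assert (reg.start_rank, reg.end_rank) == oracle == (50, 99)

    def test_matches_exhaustive_oracle_on_random_chromosomes(self, rng):
        for _ in range(30):
            n = int(rng.integers(100, 201))
            k = int(rng.integers(5, n // 2))
            ranks = sorted(rng.choice(n, size=k, replace=False).tolist())
            chrom, core = self.chrom_with_core(n, ranks)
            reg = core_region(chrom, core)
            assert (reg.start_rank, reg.end_rank) == minimal_core_interval(ranks, n)

    def test_no_core_genes_raises(self):
        chrom, _ = self.chrom_with_core(10, [])
        with pytest.raises(ValueError):
            core_region(chrom, set())


class TestArchitecture:
    def region(self, left, right):
        return CoreRegion("G", 0, 0, 1, 1, 1, 1, left, right)

    @pytest.mark.parametrize(
        "left, right, expected",
        [
            (2_000_000, 900_000, "unbalanced"),
            (1_000_000, 1_000_000, "typical"),
            (1_900_000, 1_000_000, "typical"),
            (0, 500_000, "unbalanced"),
            (0, 0, "typical"),
        ],
    )
    def test_two_to_one_rule(self, left, right, expected):
        assert classify_architecture(self.region(left, right)) == expected
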