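import numpy as np
import pytest

from linsynt import (
    conserved_adjacencies,
    goc_profile,
    heatmap_table,
    noc_profile,
    or_profile,
    read_newick,
    truth_orthology_map,
    write_profiles,
)
from linsynt.synteny import considered_genes

from conftest import make_chrom, make_map


def self_map(chrom):
    return make_map(chrom.genome_id, chrom.genome_id, [(g, g) for g in chrom.gene_ids])


def inverted(chrom, lo, hi, genome_id="inv"):
    """Copy of `chrom` with genes lo..hi (ranks) reversed and strands flipped."""
    flip = {"+": "-", "-": "+"}
    items = [(g.gene_id, g.strand) for g in chrom.genes]
    items[lo : hi + 1] = [(g, flip[s]) for g, s in reversed(items[lo : hi + 1])]
    return make_chrom(genome_id, items)


class TestConservedAdjacencies:
    def test_identical_genomes_keep_all_adjacencies(self):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(10)])
        adj = conserved_adjacencies(chrom, chrom, self_map(chrom))
        assert len(adj) == 9

    def test_internal_inversion_breaks_exactly_two(self):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(10)])
        other = inverted(chrom, 3, 6)
        omap = make_map("A", "inv", [(g, g) for g in chrom.gene_ids])
        adj = conserved_adjacencies(chrom, other, omap)
        assert len(adj) == 7
        assert ("g2", "g3") not in adj and ("g6", "g7") not in adj

    def test_no_orthologues_no_adjacencies(self):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(5)])
        other = make_chrom("B", [(f"h{i}", "+") for i in range(5)])
        assert conserved_adjacencies(chrom, other, make_map("A", "B", [])) == set()


class TestFig2Toy:
    def test_or_is_three_quarters(self, fig2_toy):
        ref, other, omap = fig2_toy
        prof = or_profile(ref, other, omap, window_pct=100)
        assert prof.values.tolist() == [0.75]

    def test_goc_is_five_sixths(self, fig2_toy):
        ref, other, omap = fig2_toy
        prof = goc_profile(ref, other, omap, window_pct=100)
        assert prof.values[0] == pytest.approx(5 / 6)

    def test_noc_excludes_isolated_orthologue(self, fig2_toy):
        ref, other, omap = fig2_toy
        assert considered_genes(ref, omap) == ["r1", "r2", "r3", "r7", "r8"]
        prof = noc_profile(ref, other, omap, window_pct=100)
        assert prof.values.tolist() == [1.0]


class TestIdentityAndEdgeCases:
    def test_all_indexes_equal_one_on_self(self):
        chrom = make_chrom("A", [(f"g{i}", "+-"[i % 2]) for i in range(60)])
        omap = self_map(chrom)
        for fn in (or_profile, goc_profile, noc_profile):
            prof = fn(chrom, chrom, omap)
            assert len(prof) > 1
            assert np.allclose(prof.values, 1.0)

    def test_disjoint_genomes_give_zero_or(self):
        ref = make_chrom("A", [(f"g{i}", "+") for i in range(40)])
        other = make_chrom("B", [(f"h{i}", "+") for i in range(40)])
        prof = or_profile(ref, other, make_map("A", "B", []))
        assert np.allclose(prof.values, 0.0)

    def test_goc_window_without_orthologues_is_na(self):
        # orthologues only in the right half; left-half windows undefined
        ref = make_chrom("A", [(f"g{i}", "+") for i in range(20)])
        other = make_chrom("B", [(f"g{i}", "+") for i in range(10, 20)])
        omap = make_map("A", "B", [(f"g{i}", f"g{i}") for i in range(10, 20)])
        prof = goc_profile(ref, other, omap, window_pct=25)  # w = 5
        assert np.isnan(prof.values[0])
        assert prof.values[-1] == pytest.approx(1.0)

    def test_complete_windows_only(self):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(10)])
        prof = or_profile(chrom, chrom, self_map(chrom), window_pct=30)  # w = 3
        assert len(prof) == 8  # n - w + 1
        assert np.all(np.diff(prof.anchors) > 0)


class TestOrderSensitivity:
    def test_or_content_only_goc_order_sensitive(self, rng):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(80)])
        omap = self_map(chrom)
        base_or = or_profile(chrom, chrom, omap).values
        base_goc = goc_profile(chrom, chrom, omap).values
        perm = rng.permutation(80)
        shuffled = make_chrom("P", [(f"g{i}", "+") for i in perm])
        omap_p = make_map("A", "P", [(g, g) for g in chrom.gene_ids])
        assert np.allclose(or_profile(chrom, shuffled, omap_p).values, base_or)
        assert np.nanmean(goc_profile(chrom, shuffled, omap_p).values) < np.nanmean(base_goc)

    def test_inversion_leaves_or_unchanged(self):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(60)])
        other = inverted(chrom, 20, 35)
        omap = make_map("A", "inv", [(g, g) for g in chrom.gene_ids])
        assert np.allclose(or_profile(chrom, other, omap).values, 1.0)
        # the inversion breaks two adjacencies, but under gene-participation
        # counting each boundary gene keeps its other conserved neighbour
        assert len(conserved_adjacencies(chrom, other, omap)) == 57

    def test_relocated_gene_lowers_goc_not_or(self):
        # moving one gene out of context leaves it without any conserved
        # neighbour: GOC drops locally while OR is order-blind
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(60)])
        ids = [f"g{i}" for i in range(60)]
        moved = ids[:10] + ids[11:40] + ["g10"] + ids[40:]
        other = make_chrom("M", [(g, "+") for g in moved])
        omap = make_map("A", "M", [(g, g) for g in ids])
        assert np.allclose(or_profile(chrom, other, omap).values, 1.0)
        goc = goc_profile(chrom, other, omap).values
        assert np.nanmin(goc) < 1.0

    def test_goc_numerator_bounded_by_denominator(self, rng):
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(100)])
        keep = rng.choice(100, size=60, replace=False)
        perm = rng.permutation([f"g{i}" for i in keep])
        other = make_chrom("B", [(g, "+") for g in perm])
        omap = make_map("A", "B", [(f"g{i}", f"g{i}") for i in keep])
        vals = goc_profile(chrom, other, omap).values
        assert np.nanmax(vals) <= 1.0 + 1e-12

    def test_random_permutation_noc_near_zero(self, rng):
        n = 1000
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(n)])
        shuffled = make_chrom("P", [(f"g{i}", "+") for i in rng.permutation(n)])
        omap = make_map("A", "P", [(g, g) for g in chrom.gene_ids])
        prof = noc_profile(chrom, shuffled, omap)
        assert np.nanmean(prof.values) < 0.05

    def test_noc_defined_where_goc_mostly_na(self, rng):
        # sparse orthology: 10 % of genes mapped, scattered
        n = 200
        chrom = make_chrom("A", [(f"g{i}", "+") for i in range(n)])
        keep = sorted(rng.choice(n, size=20, replace=False).tolist())
        # force at least one adjacent mapped pair so `considered` is non-empty
        keep = sorted(set(keep) | {50, 51})
        other = make_chrom("B", [(f"g{i}", "+") for i in keep])
        omap = make_map("A", "B", [(f"g{i}", f"g{i}") for i in keep])
        goc = goc_profile(chrom, other, omap, window_pct=2)  # w = 4 genes
        noc = noc_profile(chrom, other, omap, window_pct=50)
        assert np.isnan(goc.values).mean() > 0.3
        assert len(noc) > 0 and not np.isnan(noc.values).any()


class TestHeatmap:
    def tree(self):
        return read_newick("((A:0.05,B:0.05):0.1,C:0.3);", is_string=True)

    def test_self_row_is_one_and_rows_ordered_by_distance(self):
        ref = make_chrom("A", [(f"g{i}", "+") for i in range(50)])
        profs = []
        for other_id in ("C", "B"):
            other = make_chrom(other_id, [(f"g{i}", "+") for i in range(50)])
            omap = make_map("A", other_id, [(g, g) for g in ref.gene_ids])
            profs.append(or_profile(ref, other, omap))
        table = heatmap_table(ref, profs, self.tree(), n_bins=20)
        assert list(table.index) == ["B", "C"]  # closest first
        filled = table.loc["B"].dropna()
        assert np.allclose(filled, 1.0)

    def test_noc_profile_rejected(self):
        ref = make_chrom("A", [(f"g{i}", "+") for i in range(50)])
        omap = self_map(ref)
        prof = noc_profile(ref, ref, omap)
        with pytest.raises(ValueError, match="NOC"):
            heatmap_table(ref, [prof], self.tree())

    def test_profile_tsv_written_with_na(self, tmp_path):
        ref = make_chrom("A", [(f"g{i}", "+") for i in range(20)])
        other = make_chrom("B", [(f"g{i}", "+") for i in range(10, 20)])
        omap = make_map("A", "B", [(f"g{i}", f"g{i}") for i in range(10, 20)])
        prof = goc_profile(ref, other, omap, window_pct=25)
        out = tmp_path / "prof.tsv"
        write_profiles([prof], out)
        text = out.read_text()
        assert "NA" in text and text.startswith("index\tref\tother")
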