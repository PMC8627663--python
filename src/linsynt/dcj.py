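"""Double-cut-and-join (DCJ) rearrangement distance on linear chromosomes.

Two chromosomes restricted to their shared markers are each represented
as a signed marker order.  Every marker has a tail and a head extremity;
consecutive markers define adjacencies over extremities and the two
chromosome ends contribute telomeric (singleton) adjacencies.  In the
adjacency graph — adjacencies of the two genomes joined wherever they
share an extremity — every component is a cycle or a path, and the DCJ
distance is

    d = n - C - I/2

with n markers, C cycles and I odd paths (paths with an odd number of
edges).  The distance is divided by the marker count to compare genome
pairs with different orthologue numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .model import LinearChromosome, OrthologyMap
from .pangenome import CoreRegion

__all__ = [
    "SignedMarkerOrder",
    "DcjResult",
    "extract_marker_orders",
    "dcj_distance",
    "normalized_dcj",
    "category_dcj_scan",
]

Extremity = tuple[int, str]  # (marker_id, "t" | "h")


@dataclass(frozen=True)
class SignedMarkerOrder:
    """Ordered signed markers of one linear chromosome."""

    markers: tuple[tuple[int, int], ...]  # (marker_id, sign in {+1, -1})

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker in order")
        if any(s not in (1, -1) for _, s in self.markers):
            raise ValueError("signs must be +1 or -1")

    @property
    def marker_set(self) -> frozenset[int]:
        return frozenset(m for m, _ in self.markers)

    def adjacencies(self) -> set[frozenset[Extremity]]:
        """Adjacency set over extremities, telomeres as singletons."""
        ends = []
        for m, s in self.markers:
            left: Extremity = (m, "t") if s > 0 else (m, "h")
            right: Extremity = (m, "h") if s > 0 else (m, "t")
            ends.append((left, right))
        out: set[frozenset[Extremity]] = set()
        if not ends:
            return out
        out.add(frozenset([ends[0][0]]))
        out.add(frozenset([ends[-1][1]]))
        for (_, r), (l2, _) in zip(ends, ends[1:]):
            out.add(frozenset([r, l2]))
        return out


@dataclass(frozen=True)
class DcjResult:
    n_markers: int
    n_cycles: int
    n_odd_paths: int

    @property
    def distance(self) -> int:
        # guaranteed integer: odd paths come in pairs on two linear genomes
        return self.n_markers - self.n_cycles - self.n_odd_paths // 2

    @property
    def normalized(self) -> float:
        return normalized_dcj(self)


def dcj_distance(a: SignedMarkerOrder, b: SignedMarkerOrder) -> DcjResult:
    """DCJ distance from cycles and odd paths of the adjacency graph."""
    if a.marker_set != b.marker_set:
        raise ValueError("marker sets differ between the two orders")
    n = len(a.markers)
    adj_a = list(a.adjacencies())
    adj_b = list(b.adjacencies())
    g = nx.MultiGraph()
    g.add_nodes_from(("A", i) for i in range(len(adj_a)))
    g.add_nodes_from(("B", i) for i in range(len(adj_b)))
    where_b: dict[Extremity, int] = {}
    for j, adj in enumerate(adj_b):
        for e in adj:
            where_b[e] = j
    for i, adj in enumerate(adj_a):
        for e in adj:
            g.add_edge(("A", i), ("B", where_b[e]))
    cycles = 0
    odd_paths = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n_edges = sub.number_of_edges()
        if all(d == 2 for _, d in sub.degree()):
            cycles += 1
        elif n_edges % 2 == 1:
            odd_paths += 1
    return DcjResult(n, cycles, odd_paths)


def normalized_dcj(result: DcjResult) -> float:
    """Distance divided by the number of markers involved."""
    if result.n_markers == 0:
        raise ValueError("no markers")
    return result.distance / result.n_markers


def extract_marker_orders(
    a: LinearChromosome,
    b: LinearChromosome,
    omap: OrthologyMap,
    subset: Optional[set[str]] = None,
) -> tuple[SignedMarkerOrder, SignedMarkerOrder]:
    """Signed orders of the shared markers (optionally a gene-id subset of a).

    Markers are numbered 1..k by rank in ``a``; each genome's sign is its
    own strand with both chromosomes read left-telomere-first.
    """
    rank_b = b.rank_of()
    strand_b = {g.gene_id: g.strand for g in b.genes}
    chosen = []
    for g in a.genes:
        if g.gene_id not in omap:
            continue
        if subset is not None and g.gene_id not in subset:
            continue
        chosen.append(g)
    if not chosen:
        raise ValueError("empty marker set after filtering")
    marker_of = {g.gene_id: i + 1 for i, g in enumerate(chosen)}
    order_a = tuple(
        (marker_of[g.gene_id], 1 if g.strand == "+" else -1) for g in chosen
    )
    in_b = sorted(chosen, key=lambda g: rank_b[omap.a_to_b[g.gene_id]])
    order_b = tuple(
        (
            marker_of[g.gene_id],
            1 if strand_b[omap.a_to_b[g.gene_id]] == "+" else -1,
        )
        for g in in_b
    )
    return SignedMarkerOrder(order_a), SignedMarkerOrder(order_b)


def category_dcj_scan(
    ref: LinearChromosome,
    others: Sequence[LinearChromosome],
    maps: dict[str, OrthologyMap],
    core_gene_ids: set[str],
    region: CoreRegion,
    tree,
) -> pd.DataFrame:
    """Normalized DCJ per compared genome for three gene categories.

    Categories on the reference chromosome: ``core`` (core genes, which
    occupy the core-region by construction), ``noncore_region`` (non-core
    orthologues inside the core-region) and ``arms`` (non-core orthologues
    outside it).  Rows with an empty category carry NA.  Cophenetic
    distance to the reference is attached for regression against
    phylogenetic distance.
    """
    from .trends import cophenetic_matrix

    dist = cophenetic_matrix(tree)
    in_region = {
        g.gene_id
        for g in ref.genes
        if region.start_rank <= g.rank <= region.end_rank
    }
    categories = {
        "core": set(core_gene_ids),
        "noncore_region": {
            g.gene_id
            for g in ref.genes
            if g.gene_id in in_region and g.gene_id not in core_gene_ids
        },
        "arms": {
            g.gene_id
            for g in ref.genes
            if g.gene_id not in in_region and g.gene_id not in core_gene_ids
        },
    }
    rows = []
    for other in others:
        omap = maps[other.genome_id]
        d = dist.loc[ref.genome_id, other.genome_id]
        for cat, genes in categories.items():
            try:
                oa, ob = extract_marker_orders(ref, other, omap, subset=genes)
                res = dcj_distance(oa, ob)
                rows.append(
                    (other.genome_id, cat, res.n_markers, res.distance, res.normalized, d)
                )
            except ValueError:
                rows.append((other.genome_id, cat, 0, None, None, d))
    return pd.DataFrame(
        rows,
        columns=["other", "category", "n_markers", "distance", "normalized", "cophenetic_distance"],
    )
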