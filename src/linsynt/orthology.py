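"""Orthology assignment by reciprocal best hits and gene-family construction.

Orthologues between a pair of genomes are bidirectional best hits (BBH)
passing identity / coverage / E-value gates (defaults: >= 40 % identity,
>= 70 % coverage of both query and subject, E < 1e-10).  Genus-wide gene
families are the connected components of the union graph of all pairwise
BBH maps; components holding more than one gene from a single genome are
kept but flagged inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import OrthologyMap, SimilarityHit

__all__ = [
    "bbh_orthologs",
    "build_families",
    "FamilySet",
    "all_vs_all_protein_hits",
]


def _passes(
    h: SimilarityHit, min_id: float, min_cov: float, max_e: float
) -> bool:
    cov_ok = True
    if not np.isnan(h.q_cov):
        cov_ok = cov_ok and h.q_cov >= min_cov
    if not np.isnan(h.s_cov):
        cov_ok = cov_ok and h.s_cov >= min_cov
    return h.pct_identity >= min_id and cov_ok and h.evalue < max_e


def _best_hits(hits: Iterable[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query: max bitscore, ties by identity then subject id."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (
            (h.bitscore, h.pct_identity, _NegStr(h.subject_id))
            > (cur.bitscore, cur.pct_identity, _NegStr(cur.subject_id))
        ):
            best[h.query_id] = h
    return best


class _NegStr(str):
    """Reverses lexicographic comparison, so *smaller* ids win ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def bbh_orthologs(
    hits_ab: Sequence[SimilarityHit],
    hits_ba: Sequence[SimilarityHit],
    genome_a: str = "a",
    genome_b: str = "b",
    min_id: float = 40.0,
    min_cov: float = 70.0,
    max_e: float = 1e-10,
) -> OrthologyMap:
    """Bidirectional best hits passing the filter in both directions."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    m = OrthologyMap(genome_a, genome_b)
    for x, h in sorted(best_ab.items()):
        y = h.subject_id
        back = best_ba.get(y)
        if back is None or back.subject_id != x:
            continue
        if _passes(h, min_id, min_cov, max_e) and _passes(back, min_id, min_cov, max_e):
            m.add(x, y)
    return m


@dataclass
class FamilySet:
    """Gene families and their presence/absence across genomes."""

    presence: pd.DataFrame  # families x genomes, 0/1
    members: dict[str, list[tuple[str, str]]]  # family -> [(genome, gene)]
    inconsistent: set[str]  # families with >1 gene from one genome

    @property
    def core(self) -> list[str]:
        """Families present in every genome."""
        return list(self.presence.index[self.presence.all(axis=1)])

    @property
    def pan_size(self) -> int:
        return len(self.presence)

    def core_gene_ids(self, genome_id: str) -> set[str]:
        core = set(self.core)
        return {
            gene
            for fam in core
            for gen, gene in self.members[fam]
            if gen == genome_id
        }


def build_families(
    maps: Sequence[OrthologyMap],
    genomes: Sequence[str],
    gene_lists: Optional[dict[str, Sequence[str]]] = None,
) -> FamilySet:
    """Families = connected components of the union of all pairwise BBH maps.

    ``gene_lists`` (genome -> gene ids) adds unmapped genes as singleton
    families; without it only mapped genes form families.
    """
    g = nx.Graph()
    if gene_lists:
        for genome, genes in gene_lists.items():
            g.add_nodes_from((genome, gene) for gene in genes)
    for m in maps:
        for ga, gb in m.pairs():
            g.add_edge((m.genome_a, ga), (m.genome_b, gb))
    members: dict[str, list[tuple[str, str]]] = {}
    inconsistent: set[str] = set()
    rows = []
    for i, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        fam = f"F{i:06d}"
        comp_sorted = sorted(comp)
        members[fam] = comp_sorted
        counts: dict[str, int] = {}
        for genome, _ in comp_sorted:
            counts[genome] = counts.get(genome, 0) + 1
        if any(v > 1 for v in counts.values()):
            inconsistent.add(fam)
        rows.append([1 if gen in counts else 0 for gen in genomes])
    presence = pd.DataFrame(rows, index=list(members), columns=list(genomes), dtype=int)
    return FamilySet(presence, members, inconsistent)


def all_vs_all_protein_hits(
    prots_a: dict[str, str],
    prots_b: dict[str, str],
) -> list[SimilarityHit]:
    """All-vs-all global protein alignments as similarity hits (desk scale).

    Uses edit distance (edlib, global mode); identity = matches /
    alignment columns, coverage = alignment span over each sequence
    length, bitscore = match count, E-value 0.  Intended for small
    synthetic proteomes; use blastp output for real data.
    """
    import re

    import edlib

    hits = []
    for qid, q in prots_a.items():
        for sid, s in prots_b.items():
            res = edlib.align(q, s, mode="NW", task="path")
            cigar = res.get("cigar") or ""
            columns = sum(int(n) for n, _ in re.findall(r"(\d+)([=XIDM])", cigar))
            if columns == 0:
                continue
            matches = columns - res["editDistance"]
            if matches <= 0:
                continue
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    pct_identity=100.0 * matches / columns,
                    aln_length=columns,
                    evalue=0.0,
                    bitscore=float(matches),
                    q_cov=100.0 * min(1.0, columns / len(q)),
                    s_cov=100.0 * min(1.0, columns / len(s)),
                )
            )
    return hits
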