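"""Average nucleotide identity (ANIb), species clustering and terminal
inverted repeat (TIR) handling.

ANIb fragments the query genome into 1000 consecutive parts, aligns each
fragment to the reference, and averages the identity of fragments whose
best hit covers more than 70 % of the fragment at >= 30 % identity.  The
score is not symmetric, so the final value is the mean of the two one-way
scores.  Genomes at >= 96 % ANI are treated as conspecific when
dereplicating a genome set.

Alignment is an injected interface: anything that returns similarity hits
in the BLAST-tabular sense works.  A built-in edit-distance aligner
(edlib, infix mode) is provided for desk-scale synthetic genomes; blastn
or any other external tool can be substituted through the same protocol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .model import GeneRecord, LinearChromosome, SimilarityHit

__all__ = [
    "AnibResult",
    "TirCall",
    "fragment_genome",
    "anib_oneway",
    "anib_pair",
    "cluster_species",
    "detect_tir",
    "trim_tir",
    "EdlibFragmentAligner",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnibResult:
    genome_a: str
    genome_b: str
    oneway_ab: Optional[float]
    oneway_ba: Optional[float]

    @property
    def final(self) -> Optional[float]:
        """Mean of the two reciprocal one-way scores (None if either is undefined)."""
        if self.oneway_ab is None or self.oneway_ba is None:
            return None
        return (self.oneway_ab + self.oneway_ba) / 2.0


@dataclass(frozen=True)
class TirCall:
    genome_id: str
    tir_length_bp: int
    pct_identity: float


def fragment_genome(seq: str, n_fragments: int = 1000) -> list[tuple[str, str]]:
    """Split a genome into ``n_fragments`` consecutive, non-overlapping parts.

    Fragment lengths differ by at most one base: the last ``len(seq) %
    n_fragments`` fragments each carry one extra base.  Returns
    ``(fragment_id, sequence)`` pairs with ids ``frag000000`` ...
    """
    if len(seq) < n_fragments:
        raise ValueError(f"sequence length {len(seq)} < {n_fragments} fragments")
    base, rem = divmod(len(seq), n_fragments)
    frags = []
    pos = 0
    for i in range(n_fragments):
        size = base + (1 if i >= n_fragments - rem else 0)
        frags.append((f"frag{i:06d}", seq[pos : pos + size]))
        pos += size
    return frags


class FragmentAligner(Protocol):
    """Anything that aligns query fragments against a target genome."""

    def align(self, fragments: Sequence[tuple[str, str]], target: str) -> list[SimilarityHit]:
        ...


class EdlibFragmentAligner:
    """Infix edit-distance alignment of each fragment against the target.

    Each fragment is aligned against the target and its reverse complement
    (best of the two kept).  Identity is computed from the alignment CIGAR
    as matches / alignment columns; the whole fragment is aligned (infix
    mode), so the alignment length is at least the fragment length.
    Bitscore is the match count, which makes best-hit selection by
    bitscore equivalent to best-by-alignment-quality.
    """

    def __init__(self, max_divergence: float = 0.5) -> None:
        # Edit-distance cap as a fraction of fragment length; alignments
        # worse than this report no hit, mirroring a failed BLAST match.
        self.max_divergence = max_divergence

    def _one(self, frag: str, target: str) -> Optional[tuple[float, int, int]]:
        k = max(1, int(self.max_divergence * len(frag)))
        res = edlib.align(frag, target, mode="HW", task="path", k=k)
        if res["editDistance"] < 0 or not res.get("cigar"):
            return None
        columns = sum(int(n) for n, _ in re.findall(r"(\d+)([=XIDM])", res["cigar"]))
        matches = columns - res["editDistance"]
        return 100.0 * matches / columns, columns, matches

    def align(self, fragments: Sequence[tuple[str, str]], target: str) -> list[SimilarityHit]:
        target_rc = _revcomp(target)
        hits = []
        for frag_id, frag in fragments:
            best = None
            for t in (target, target_rc):
                r = self._one(frag, t)
                if r is not None and (best is None or r[2] > best[2]):
                    best = r
            if best is None:
                continue
            identity, columns, matches = best
            hits.append(
                SimilarityHit(
                    query_id=frag_id,
                    subject_id="target",
                    pct_identity=identity,
                    aln_length=columns,
                    evalue=0.0,
                    bitscore=float(matches),
                )
            )
        return hits


def anib_oneway(
    fragments: Sequence[tuple[str, str]],
    hits: Sequence[SimilarityHit],
    min_coverage: float = 70.0,
    min_identity: float = 30.0,
) -> Optional[float]:
    """One-way ANIb: mean identity of fragments with a qualifying best hit.

    The best hit per fragment (highest bitscore) qualifies when its
    alignment length exceeds ``min_coverage`` % of the fragment length and
    its identity is at least ``min_identity`` %.  Fragments without a
    qualifying hit are excluded from the mean; if no fragment qualifies
    the score is undefined (None), not 0.
    """
    frag_len = {fid: len(s) for fid, s in fragments}
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_id not in frag_len:
            continue
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.query_id] = h
    kept = [
        h.pct_identity
        for fid, h in best.items()
        if h.aln_length > min_coverage / 100.0 * frag_len[fid]
        and h.pct_identity >= min_identity
    ]
    if not kept:
        return None
    return float(np.mean(kept))


def anib_pair(
    genome_a: str,
    genome_b: str,
    seq_a: str,
    seq_b: str,
    aligner: Optional[FragmentAligner] = None,
    n_fragments: int = 1000,
) -> AnibResult:
    """Reciprocal ANIb between two genomes; final = mean of the one-way scores."""
    if aligner is None:
        aligner = EdlibFragmentAligner()
    frags_a = fragment_genome(seq_a, n_fragments)
    frags_b = fragment_genome(seq_b, n_fragments)
    ab = anib_oneway(frags_a, aligner.align(frags_a, seq_b))
    ba = anib_oneway(frags_b, aligner.align(frags_b, seq_a))
    return AnibResult(genome_a, genome_b, ab, ba)


def cluster_species(
    ani_matrix: pd.DataFrame,
    threshold: float = 96.0,
    genome_lengths: Optional[dict[str, int]] = None,
) -> list[tuple[list[str], str]]:
    """Single-linkage species clusters over the >= threshold ANI relation.

    Returns ``(members, representative)`` per cluster; the representative
    is the largest genome (by ``genome_lengths``) or the lexicographically
    first member when lengths are not given.  Every genome lands in
    exactly one cluster.
    """
    ids = list(ani_matrix.index)
    if list(ani_matrix.columns) != ids:
        raise ValueError("ANI matrix must be square with matching index/columns")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if ani_matrix.loc[a, b] >= threshold:
                g.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if genome_lengths:
            rep = max(members, key=lambda m: (genome_lengths.get(m, 0), m))
        else:
            rep = members[0]
        clusters.append((members, rep))
    clusters.sort(key=lambda c: c[0][0])
    return clusters


def detect_tir(
    seq: str,
    genome_id: str = "",
    min_len: int = 50,
    min_identity: float = 99.0,
    mismatch_penalty: int = 10,
    xdrop: int = 50,
) -> TirCall:
    """Detect a terminal inverted repeat by anchor-and-extend from the termini.

    The prefix is compared position-by-position with the reverse
    complement of the suffix (both anchored at the chromosome ends).  The
    extension scores +1 per match and ``-mismatch_penalty`` per mismatch
    and stops once the running score drops ``xdrop`` below its maximum;
    the repeat ends at the score maximum (trailing mismatches trimmed).
    The call is reported when the repeat is at least ``min_len`` long with
    overall identity >= ``min_identity`` %; otherwise length 0.
    """
    n = len(seq)
    limit = n // 2
    s = seq.upper()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    score = 0
    best_score = 0
    best_len = 0
    mismatches = 0
    best_mismatches = 0
    for i in range(limit):
        a = s[i]
        b = comp.get(s[n - 1 - i], "N")
        if a == b and a in "ACGT":
            score += 1
        else:
            score -= mismatch_penalty
            mismatches += 1
        if score > best_score:
            best_score = score
            best_len = i + 1
            best_mismatches = mismatches
        if score < best_score - xdrop:
            break
    if best_len == 0:
        return TirCall(genome_id, 0, 0.0)
    identity = 100.0 * (best_len - best_mismatches) / best_len
    if best_len < min_len or identity < min_identity:
        return TirCall(genome_id, 0, 0.0)
    return TirCall(genome_id, best_len, identity)


def trim_tir(
    seq: str,
    call: TirCall,
    chrom: Optional[LinearChromosome] = None,
) -> tuple[str, Optional[LinearChromosome]]:
    """Keep a single copy of the TIR: remove the right-end copy.

    Genes entirely within the removed span are dropped; a gene straddling
    the trim boundary is truncated out with a warning.  Returns the
    trimmed sequence and, when a chromosome is given, the updated
    chromosome (ranks reassigned).
    """
    import warnings

    tir = call.tir_length_bp
    if tir == 0:
        return seq, chrom
    if tir >= len(seq) / 2:
        raise ValueError("TIR longer than half the sequence")
    new_len = len(seq) - tir
    new_seq = seq[:new_len]
    new_chrom = None
    if chrom is not None:
        kept: list[GeneRecord] = []
        for g in chrom.genes:
            if g.end <= new_len:
                kept.append(g)
            elif g.start <= new_len:
                warnings.warn(
                    f"{chrom.genome_id}: gene {g.gene_id} straddles the TIR trim "
                    "boundary; removed"
                )
        new_chrom = LinearChromosome.from_unordered(
            chrom.genome_id, kept, length_bp=new_len, tir_length_bp=0
        )
    return new_seq, new_chrom
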