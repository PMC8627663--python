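"""Core in-memory containers shared across the package.

A genome is modelled as a single linear replicon carrying an ordered,
stranded list of genes.  Coordinates are 1-based inclusive (GFF3
convention); gene ranks are 0-based, counted from the left telomere.
Terminal inverted repeats (TIRs), when present, are recorded as a length
in base pairs on the chromosome object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

__all__ = [
    "GeneRecord",
    "LinearChromosome",
    "SimilarityHit",
    "OrthologyMap",
]


@dataclass(frozen=True)
class GeneRecord:
    """One gene on a linear chromosome.

    Parameters
    ----------
    gene_id:
        Identifier, unique within its genome.
    genome_id:
        Identifier of the genome the gene belongs to.
    rank:
        0-based position index along the chromosome, left telomere first.
    start, end:
        1-based inclusive coordinates, ``start <= end``.
    strand:
        ``"+"`` or ``"-"``.
    family_id:
        Optional gene-family label (simulator ground truth or an assigned
        orthology family).
    protein_seq:
        Optional amino-acid sequence.
    """

    gene_id: str
    genome_id: str
    rank: int
    start: int
    end: int
    strand: str
    family_id: Optional[str] = None
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: unknown strand symbol {self.strand!r}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class LinearChromosome:
    """An ordered, stranded gene list on one linear replicon."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    length_bp: int = 0
    tir_length_bp: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for i, g in enumerate(self.genes):
            if g.rank != i:
                raise ValueError(
                    f"{self.genome_id}: rank {g.rank} at list position {i}; "
                    "ranks must be 0..n-1 in order"
                )
            if g.gene_id in seen:
                raise ValueError(f"{self.genome_id}: duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
        if self.genes:
            if self.length_bp and max(g.end for g in self.genes) > self.length_bp:
                raise ValueError(f"{self.genome_id}: gene end beyond length_bp")
        if self.length_bp and self.tir_length_bp > self.length_bp / 2:
            raise ValueError(f"{self.genome_id}: TIR longer than half the chromosome")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def rank_of(self) -> dict[str, int]:
        """Map gene_id -> rank."""
        return {g.gene_id: g.rank for g in self.genes}

    @classmethod
    def from_unordered(
        cls,
        genome_id: str,
        genes: Sequence[GeneRecord],
        length_bp: int = 0,
        tir_length_bp: int = 0,
    ) -> "LinearChromosome":
        """Build a chromosome from genes in arbitrary order.

        Genes are sorted by ``start`` (ties by ``end`` then ``gene_id``) and
        ranks reassigned 0..n-1.
        """
        ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
        ranked = [replace(g, rank=i, genome_id=genome_id) for i, g in enumerate(ordered)]
        if not length_bp and ranked:
            length_bp = max(g.end for g in ranked)
        return cls(genome_id, ranked, length_bp, tir_length_bp)


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a pairwise similarity search (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    q_cov: float = float("nan")
    s_cov: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1, got {self.aln_length}")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


class OrthologyMap:
    """One-to-one gene mapping between a pair of genomes.

    The mapping is injective in both directions; attempts to map an
    already-mapped gene raise ``ValueError``.
    """

    def __init__(self, genome_a: str, genome_b: str) -> None:
        self.genome_a = genome_a
        self.genome_b = genome_b
        self.a_to_b: dict[str, str] = {}
        self.b_to_a: dict[str, str] = {}

    def add(self, gene_a: str, gene_b: str) -> None:
        if gene_a in self.a_to_b or gene_b in self.b_to_a:
            raise ValueError(f"mapping not one-to-one: ({gene_a}, {gene_b})")
        self.a_to_b[gene_a] = gene_b
        self.b_to_a[gene_b] = gene_a

    def __len__(self) -> int:
        return len(self.a_to_b)

    def __contains__(self, gene_a: str) -> bool:
        return gene_a in self.a_to_b

    def pairs(self) -> list[tuple[str, str]]:
        return list(self.a_to_b.items())

    def reversed(self) -> "OrthologyMap":
        m = OrthologyMap(self.genome_b, self.genome_a)
        m.a_to_b = dict(self.b_to_a)
        m.b_to_a = dict(self.a_to_b)
        return m
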