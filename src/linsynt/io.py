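"""Readers and writers for the standard formats the pipeline consumes.

Supported inputs: TSV gene tables, GFF3 restricted to CDS features,
BLAST tabular (outfmt 6, optionally with a trailing qcovs column),
Newick trees and FASTA sequences.  Coordinates follow the GFF3
convention (1-based, inclusive).
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Optional, Union

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneRecord, LinearChromosome, SimilarityHit

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "read_blast_tab",
    "read_newick",
    "read_fasta",
    "write_fasta",
]

PathLike = Union[str, Path]

_TSV_COLUMNS = ("gene_id", "start", "end", "strand")


def read_gene_table(path: PathLike, genome_id: str) -> LinearChromosome:
    """Read a gene table (TSV or GFF3) into a :class:`LinearChromosome`.

    TSV tables need a header with at least ``gene_id, start, end, strand``
    and may carry ``family_id``.  GFF3 input is restricted to CDS features
    on a single sequence region.  Genes are sorted by start coordinate and
    ranks assigned 0..n-1; duplicate gene ids are an error, overlapping
    genes are not.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("##gff-version") or "\tCDS\t" in first:
        return _read_gff3(path, genome_id)
    return _read_tsv(path, genome_id)


def _read_tsv(path: Path, genome_id: str) -> LinearChromosome:
    genes: list[GeneRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        return LinearChromosome(genome_id, [])
    header = [c.strip() for c in rows[0]]
    missing = [c for c in _TSV_COLUMNS if c not in header]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in header}
    for row in rows[1:]:
        genes.append(
            GeneRecord(
                gene_id=row[idx["gene_id"]],
                genome_id=genome_id,
                rank=0,
                start=int(row[idx["start"]]),
                end=int(row[idx["end"]]),
                strand=row[idx["strand"]],
                family_id=row[idx["family_id"]] if "family_id" in idx and row[idx["family_id"]] else None,
            )
        )
    return LinearChromosome.from_unordered(genome_id, genes)


def _read_gff3(path: Path, genome_id: str) -> LinearChromosome:
    genes: list[GeneRecord] = []
    seqids: set[str] = set()
    length_bp = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    length_bp = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            seqids.add(cols[0])
            if len(seqids) > 1:
                raise ValueError(f"{path}: CDS features on more than one sequence region")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if gene_id is None:
                raise ValueError(f"{path}: CDS without ID attribute")
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    rank=0,
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    family_id=attrs.get("family_id"),
                )
            )
    return LinearChromosome.from_unordered(genome_id, genes, length_bp=length_bp)


def write_gene_table(chrom: LinearChromosome, path: PathLike) -> None:
    """Write a chromosome as a TSV gene table (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tstart\tend\tstrand\tfamily_id\n")
        for g in chrom.genes:
            fh.write(
                f"{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}\t{g.family_id or ''}\n"
            )


def read_blast_tab(path: PathLike) -> list[SimilarityHit]:
    """Read BLAST tabular output (outfmt 6, optional 13th qcovs column).

    Multiple hits per query are preserved in file order.
    """
    hits: list[SimilarityHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 columns, got {len(cols)}")
            try:
                pct = float(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric identity {cols[2]!r}") from exc
            qcov = float(cols[12]) if len(cols) > 12 else float("nan")
            hits.append(
                SimilarityHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=pct,
                    aln_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    q_cov=qcov,
                )
            )
    return hits


def read_newick(source: PathLike, *, is_string: bool = False) -> dendropy.Tree:
    """Read a single Newick tree.

    Leaf labels must be unique; missing branch lengths trigger a warning
    and are treated as 0.
    """
    try:
        if is_string:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
    except Exception as exc:  # dendropy raises schema-specific error classes
        raise ValueError(f"invalid Newick input: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
        elif edge.length < 0:
            raise ValueError("negative branch length")
    if n_missing:
        warnings.warn(f"{n_missing} branch lengths missing; treated as 0")
    return tree


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
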