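"""Sliding-window synteny indexes for pairwise chromosome comparisons.

Three indexes, all computed on a reference chromosome against a compared
genome through an orthology map:

* OR (orthology rate): fraction of the window's genes that have an
  orthologue in the compared genome.  Content-only, order-blind.
* GOC (gene order conservation): fraction of the window's orthologues
  that take part in at least one conserved adjacency (rank-adjacent in
  the reference and rank-adjacent in the compared genome).  Undefined
  (NA) when the window has no orthologues.
* NOC (neighbour orthologue conservation): like GOC but computed over
  the "considered" genes only — orthologues with at least one
  rank-neighbour that is also an orthologue (isolated orthologues are
  excluded), which keeps the index defined under sparse orthology.

OR and GOC windows are anchored at the chromosomal position of their
central gene; NOC windows slide over the considered genes and are
reported by ordinal window number without chromosomal anchoring.
Adjacency conservation ignores strand; orientation is handled by the
rearrangement distance, not by these indexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import LinearChromosome, OrthologyMap

__all__ = [
    "WindowProfile",
    "conserved_adjacencies",
    "or_profile",
    "goc_profile",
    "noc_profile",
    "heatmap_table",
    "write_profiles",
]


@dataclass
class WindowProfile:
    index_kind: str  # "OR", "GOC" or "NOC"
    ref_id: str
    other_id: str
    window_size: int
    anchors: np.ndarray  # bp of central gene (OR/GOC) or ordinal number (NOC)
    values: np.ndarray  # in [0, 1]; NaN encodes NA

    def __len__(self) -> int:
        return len(self.values)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def conserved_adjacencies(
    ref: LinearChromosome,
    other: LinearChromosome,
    omap: OrthologyMap,
) -> set[tuple[str, str]]:
    """Rank-adjacent reference pairs whose images are rank-adjacent too.

    Orientation is ignored: the pair (g_i, g_{i+1}) is conserved iff both
    genes are mapped and their orthologues' ranks in ``other`` differ by
    exactly 1 in either direction.
    """
    rank_other = other.rank_of()
    out = set()
    for g1, g2 in zip(ref.genes, ref.genes[1:]):
        if g1.gene_id in omap and g2.gene_id in omap:
            r1 = rank_other[omap.a_to_b[g1.gene_id]]
            r2 = rank_other[omap.a_to_b[g2.gene_id]]
            if abs(r1 - r2) == 1:
                out.add((g1.gene_id, g2.gene_id))
    return out


def _window_size(n: int, window_pct: float) -> int:
    w = max(1, _round_half_up(window_pct / 100.0 * n))
    if w > n:
        raise ValueError(f"window of {w} genes exceeds chromosome of {n} genes")
    return w


def or_profile(
    ref: LinearChromosome,
    other: LinearChromosome,
    omap: OrthologyMap,
    window_pct: float = 5.0,
) -> WindowProfile:
    """Orthology rate in a sliding window (one-gene step, complete windows only)."""
    n = len(ref)
    w = _window_size(n, window_pct)
    mapped = np.array([g.gene_id in omap for g in ref.genes], dtype=float)
    counts = np.convolve(mapped, np.ones(w), mode="valid")
    anchors = np.array(
        [ref.genes[i + w // 2].midpoint for i in range(n - w + 1)]
    )
    return WindowProfile("OR", ref.genome_id, other.genome_id, w, anchors, counts / w)


def goc_profile(
    ref: LinearChromosome,
    other: LinearChromosome,
    omap: OrthologyMap,
    window_pct: float = 5.0,
) -> WindowProfile:
    """Gene order conservation in a sliding window (NA where no orthologues)."""
    n = len(ref)
    w = _window_size(n, window_pct)
    adj = conserved_adjacencies(ref, other, omap)
    in_pair = {g for pair in adj for g in pair}
    mapped = np.array([g.gene_id in omap for g in ref.genes], dtype=float)
    paired = np.array([g.gene_id in in_pair for g in ref.genes], dtype=float)
    denom = np.convolve(mapped, np.ones(w), mode="valid")
    numer = np.convolve(paired, np.ones(w), mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, numer / np.maximum(denom, 1e-12), np.nan)
    anchors = np.array(
        [ref.genes[i + w // 2].midpoint for i in range(n - w + 1)]
    )
    return WindowProfile("GOC", ref.genome_id, other.genome_id, w, anchors, values)


def considered_genes(
    ref: LinearChromosome,
    omap: OrthologyMap,
) -> list[str]:
    """Mapped genes with >= 1 rank-neighbour (either side) also mapped."""
    mapped = [g.gene_id in omap for g in ref.genes]
    out = []
    n = len(ref)
    for i, g in enumerate(ref.genes):
        if not mapped[i]:
            continue
        left = mapped[i - 1] if i > 0 else False
        right = mapped[i + 1] if i < n - 1 else False
        if left or right:
            out.append(g.gene_id)
    return out


def noc_profile(
    ref: LinearChromosome,
    other: LinearChromosome,
    omap: OrthologyMap,
    window_pct: float = 5.0,
    step_pct: float = 0.1,
) -> WindowProfile:
    """Neighbour orthologue conservation over the considered genes.

    Windows hold ``window_pct`` % of the considered genes and advance by
    ``step_pct`` % (at least one gene); values are the fraction of the
    window's genes participating in a conserved adjacency.  Anchors are
    ordinal window numbers (no chromosomal anchoring).
    """
    cons = considered_genes(ref, omap)
    if not cons:
        return WindowProfile(
            "NOC", ref.genome_id, other.genome_id, 0, np.array([]), np.array([])
        )
    adj = conserved_adjacencies(ref, other, omap)
    in_pair = {g for pair in adj for g in pair}
    flags = np.array([g in in_pair for g in cons], dtype=float)
    m = len(cons)
    w = max(1, _round_half_up(window_pct / 100.0 * m))
    step = max(1, _round_half_up(step_pct / 100.0 * m))
    starts = list(range(0, m - w + 1, step))
    values = np.array([flags[s : s + w].mean() for s in starts])
    anchors = np.arange(len(starts), dtype=float)
    return WindowProfile("NOC", ref.genome_id, other.genome_id, w, anchors, values)


def heatmap_table(
    ref: LinearChromosome,
    profiles: list[WindowProfile],
    tree,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Per-genome profile rows binned into percentiles of the reference.

    Rows (one per compared genome) are ordered from the closest to the
    farthest relative to the reference by cophenetic distance; columns are
    ``n_bins`` equal spans of the reference chromosome length holding the
    mean of the window values anchored inside them (NaN where a bin holds
    no window or only NA values).  Profiles must be chromosome-anchored
    (OR/GOC); NOC profiles have no physical anchors and are rejected.
    """
    from .trends import cophenetic_matrix

    for p in profiles:
        if p.index_kind == "NOC":
            raise ValueError("NOC profiles are not chromosome-anchored; no heatmap")
        if p.ref_id != ref.genome_id:
            raise ValueError("profile reference does not match ref chromosome")
    dist = cophenetic_matrix(tree)
    if ref.genome_id not in dist.index:
        raise ValueError(f"{ref.genome_id} missing from tree")
    for p in profiles:
        if p.other_id not in dist.index:
            raise ValueError(f"{p.other_id} missing from tree")
    edges = np.linspace(0, ref.length_bp, n_bins + 1)
    rows = {}
    for p in profiles:
        binned = np.full(n_bins, np.nan)
        idx = np.clip(np.searchsorted(edges, p.anchors, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            vals = p.values[idx == b]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                binned[b] = vals.mean()
        rows[p.other_id] = binned
    order = sorted(rows, key=lambda g: dist.loc[ref.genome_id, g])
    return pd.DataFrame(
        [rows[g] for g in order],
        index=order,
        columns=[f"pct{b + 1:03d}" for b in range(n_bins)],
    )


def write_profiles(profiles: list[WindowProfile], path) -> None:
    """Tidy TSV (index, ref, other, anchor, value); NA written literally."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("index\tref\tother\tanchor\tvalue\n")
        for p in profiles:
            for a, v in zip(p.anchors, p.values):
                val = "NA" if np.isnan(v) else f"{v:.6g}"
                fh.write(f"{p.index_kind}\t{p.ref_id}\t{p.other_id}\t{a:g}\t{val}\n")
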