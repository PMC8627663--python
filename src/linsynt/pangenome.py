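"""Pan/core-genome rarefaction, Heap's-law fit and core-region delimitation.

The core-genome is the set of families present in every genome; the
pan-genome is every family seen at least once.  Rarefaction resamples
random genome subsets (100 iterations per subset size) to trace both
curves.  Openness is summarized by Heap's law, pan(n) ~ kappa * n**gamma.

On each chromosome, the core-region is the shortest contiguous rank
interval containing at least 95 % of that genome's core genes; the
flanking spans are the chromosomal arms.  A chromosome is called
unbalanced when one arm is at least twice as long as the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import LinearChromosome
from .orthology import FamilySet

__all__ = [
    "CoreRegion",
    "rarefaction",
    "heaps_fit",
    "core_region",
    "classify_architecture",
]


@dataclass(frozen=True)
class CoreRegion:
    genome_id: str
    start_rank: int
    end_rank: int
    start_bp: int
    end_bp: int
    n_core_contained: int
    n_core_total: int
    left_arm_bp: int
    right_arm_bp: int


def rarefaction(
    families: FamilySet,
    n_range: Optional[Sequence[int]] = None,
    iterations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Core/pan sizes over random genome subsets.

    For each subset size ``n``, draws ``iterations`` random n-subsets of
    genomes (without replacement within a subset) and records the number
    of families present in all (core) and in at least one (pan) of them.
    Returns a tidy frame (n, iteration, core_size, pan_size).
    """
    mat = families.presence.to_numpy(dtype=bool)
    n_genomes = mat.shape[1]
    if n_range is None:
        n_range = range(2, n_genomes + 1)
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_range:
        if n > n_genomes:
            raise ValueError(f"subset size {n} > {n_genomes} genomes")
        for it in range(iterations):
            cols = rng.choice(n_genomes, size=n, replace=False)
            sub = mat[:, cols]
            rows.append((n, it, int(sub.all(axis=1).sum()), int(sub.any(axis=1).sum())))
    return pd.DataFrame(rows, columns=["n", "iteration", "core_size", "pan_size"])


def heaps_fit(pan_medians: pd.Series | dict[int, float]) -> tuple[float, float]:
    """Fit Heap's law pan(n) = kappa * n**gamma by log-log least squares.

    ``pan_medians`` maps subset size n to the median pan-genome size.
    Returns (kappa, gamma); gamma > 0 indicates an open pan-genome.
    """
    s = pd.Series(pan_medians).sort_index()
    if len(s) < 3:
        raise ValueError("need at least 3 points")
    if (s <= 0).any() or (s.index <= 0).any():
        raise ValueError("sizes and n must be positive")
    gamma, logk = np.polyfit(np.log(s.index.to_numpy(float)), np.log(s.to_numpy(float)), 1)
    return float(np.exp(logk)), float(gamma)


def core_region(
    chrom: LinearChromosome,
    core_gene_ids: set[str],
    fraction: float = 0.95,
) -> CoreRegion:
    """Shortest rank interval containing >= ceil(fraction * core count) core genes.

    Candidate intervals start and end on core genes; among minimal-span
    candidates the most central one (midpoint closest to the chromosome
    midpoint, then smaller start) is kept.  Arm sizes are the base pairs
    left of the interval start and right of the interval end.
    """
    pos = sorted(g.rank for g in chrom if g.gene_id in core_gene_ids)
    if not pos:
        raise ValueError(f"{chrom.genome_id}: no core genes")
    total = len(pos)
    need = int(np.ceil(fraction * total))
    n = len(chrom)
    centre = (n - 1) / 2.0
    best = None
    for i in range(total - need + 1):
        lo, hi = pos[i], pos[i + need - 1]
        span = hi - lo + 1
        key = (span, abs((lo + hi) / 2.0 - centre), lo)
        if best is None or key < best[0]:
            best = (key, lo, hi)
    _, lo, hi = best
    start_bp = chrom.genes[lo].start
    end_bp = chrom.genes[hi].end
    return CoreRegion(
        genome_id=chrom.genome_id,
        start_rank=lo,
        end_rank=hi,
        start_bp=start_bp,
        end_bp=end_bp,
        n_core_contained=need,
        n_core_total=total,
        left_arm_bp=start_bp - 1,
        right_arm_bp=max(chrom.length_bp - end_bp, 0),
    )


def classify_architecture(region: CoreRegion, ratio: float = 2.0) -> str:
    """'unbalanced' when one arm is at least ``ratio`` times the other."""
    arms = sorted((region.left_arm_bp, region.right_arm_bp))
    if arms[1] == 0:
        return "typical"
    if arms[0] == 0:
        return "unbalanced"
    return "unbalanced" if arms[1] / arms[0] >= ratio else "typical"
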