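"""Portion-wise evolutionary-rate trends along the chromosome.

The reference chromosome is split into k portions holding equal gene
numbers; per portion, OR or GOC is computed against every other genome
(the portion treated as a single window) and regressed against the
cophenetic (phylogenetic) distance with a polynomial.  The early-
divergence slope is a plain linear fit restricted to the distance range
[0, 0.1], which is where closely related genome pairs separate the fast-
evolving terminal portions from the conserved central ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .model import LinearChromosome, OrthologyMap
from .synteny import conserved_adjacencies

__all__ = [
    "PortionScheme",
    "TrendFit",
    "cophenetic_matrix",
    "split_portions",
    "portion_index_scan",
    "fit_trend",
]


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf patristic distances (sum of branch lengths on the path)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    mat = np.zeros((len(taxa), len(taxa)))
    for i, t1 in enumerate(taxa):
        for j, t2 in enumerate(taxa):
            if i < j:
                d = pdm.patristic_distance(t1, t2)
                mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass(frozen=True)
class PortionScheme:
    """Contiguous rank blocks of near-equal gene counts partitioning 0..n-1."""

    k: int
    intervals: tuple[tuple[int, int], ...]  # inclusive (start_rank, end_rank)


def split_portions(chrom: LinearChromosome, k: int) -> PortionScheme:
    """Split the chromosome into k contiguous portions of equal gene counts.

    The first portions hold ``n // k`` genes; the last ``n % k`` portions
    hold one gene more.
    """
    n = len(chrom)
    if k > n:
        raise ValueError(f"k={k} exceeds gene count {n}")
    base, rem = divmod(n, k)
    intervals = []
    start = 0
    for i in range(k):
        size = base + (1 if i >= k - rem else 0)
        intervals.append((start, start + size - 1))
        start += size
    return PortionScheme(k, tuple(intervals))


def portion_index_scan(
    ref: LinearChromosome,
    others: Sequence[LinearChromosome],
    maps: dict[str, OrthologyMap],
    scheme: PortionScheme,
    index_kind: str = "OR",
    tree: Optional[dendropy.Tree] = None,
) -> pd.DataFrame:
    """OR or GOC per portion and compared genome (portion = one window).

    Returns a tidy frame (portion, other, value[, distance]); GOC is NA
    for portions without orthologues.  Portions are numbered from 1 at the
    left telomere.
    """
    if index_kind not in ("OR", "GOC"):
        raise ValueError("index_kind must be 'OR' or 'GOC'")
    dist = cophenetic_matrix(tree) if tree is not None else None
    rows = []
    for other in others:
        omap = maps[other.genome_id]
        if index_kind == "GOC":
            adj = conserved_adjacencies(ref, other, omap)
            in_pair = {g for pair in adj for g in pair}
        for p, (lo, hi) in enumerate(scheme.intervals, start=1):
            genes = ref.genes[lo : hi + 1]
            mapped = [g.gene_id for g in genes if g.gene_id in omap]
            if index_kind == "OR":
                value = len(mapped) / len(genes)
            else:
                value = (
                    sum(g in in_pair for g in mapped) / len(mapped)
                    if mapped
                    else np.nan
                )
            row = dict(portion=p, other=other.genome_id, value=value)
            if dist is not None:
                row["distance"] = dist.loc[ref.genome_id, other.genome_id]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """Polynomial trend of an index against phylogenetic distance."""

    degree: int
    coefficients: np.ndarray  # numpy polyfit convention, highest power first
    alpha_early: float  # linear slope over the early distance range
    early_range: tuple[float, float]
    n_points: int
    n_points_early: int
    residual_std: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))


def fit_trend(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
    degree: int = 3,
    early_range: tuple[float, float] = (0.0, 0.1),
) -> TrendFit:
    """Least-squares polynomial trend plus early-divergence slope.

    ``points`` holds (distance, value) pairs; NA values are dropped.  The
    early slope is an ordinary linear fit over points whose distance falls
    inside ``early_range`` (NaN when fewer than two such points); it is
    the explicit estimator of the "curve slope" near the origin rather
    than the polynomial's derivative.
    """
    if isinstance(points, pd.DataFrame):
        arr = points[["distance", "value"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
    arr = arr[~np.isnan(arr).any(axis=1)]
    if len(arr) < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for degree {degree}")
    x, y = arr[:, 0], arr[:, 1]
    with warnings.catch_warnings():
        # constant or near-collinear inputs are legitimate (e.g. no divergence)
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(x, y, degree)
    resid = y - np.polyval(coeffs, x)
    dof = max(len(x) - (degree + 1), 1)
    residual_std = float(np.sqrt((resid**2).sum() / dof))
    lo, hi = early_range
    sel = (x >= lo) & (x <= hi)
    if sel.sum() >= 2 and np.ptp(x[sel]) > 0:
        slope = float(np.polyfit(x[sel], y[sel], 1)[0])
    elif sel.sum() >= 2:
        slope = 0.0
    else:
        slope = float("nan")
    return TrendFit(
        degree=degree,
        coefficients=coeffs,
        alpha_early=slope,
        early_range=early_range,
        n_points=len(x),
        n_points_early=int(sel.sum()),
        residual_std=residual_std,
    )


def confidence_band(
    fit: TrendFit,
    x_fit: np.ndarray,
    y_fit: np.ndarray,
    x_new: np.ndarray,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise confidence band for the fitted polynomial mean response."""
    x_fit = np.asarray(x_fit, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    X = np.vander(x_fit, fit.degree + 1)
    Xn = np.vander(x_new, fit.degree + 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = fit.residual_std * np.sqrt(np.einsum("ij,jk,ik->i", Xn, XtX_inv, Xn))
    dof = max(len(x_fit) - (fit.degree + 1), 1)
    tval = stats.t.ppf(0.5 + level / 2, dof)
    mean = fit.predict(x_new)
    return mean - tval * se, mean + tval * se
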