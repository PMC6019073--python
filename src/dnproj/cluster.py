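"""Correlation-distance hierarchical clustering, implemented from first principles.

Innervation profiles (rows = DN types, columns = neuropils) are compared
with Pearson's correlation; the dissimilarity between two profiles is
``d = 1 - r`` (range [0, 2]).  Agglomeration uses unweighted average
linkage (UPGMA on the dissimilarity): at each step the pair of clusters
with the smallest mean pairwise dissimilarity is merged at that mean, and
distances to the merged cluster are maintained with the size-weighted
Lance-Williams update.  Ties are broken deterministically by the smallest
leaf indices of the candidate pair.

Zero-variance profiles (all-0 or all-1) have no defined correlation;
by default they are excluded from the analysis and reported, mirroring the
convention of omitting uninnervated regions.  An alternative policy assigns
them the maximal distance 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import InnervationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "CorrelationMatrix",
    "Dendrogram",
    "ZeroVarianceError",
    "pearson_correlation",
    "correlation_distance_matrix",
    "autocorrelation",
    "average_linkage",
    "cut_dendrogram",
    "to_newick",
]


class ZeroVarianceError(ValueError):
    """Correlation requested for a constant profile."""


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient.

    On binary vectors this equals the phi coefficient.  Raises
    :class:`ZeroVarianceError` for constant input rather than silently
    returning 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("correlation undefined for a zero-variance profile")
    r = float(xc @ yc) / (sx * sy)
    return max(-1.0, min(1.0, r))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str = "correlation"
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class CorrelationMatrix:
    labels: list[str]
    values: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("correlation matrix shape does not match labels")
        if (np.abs(v) > 1 + 1e-12).any():
            raise ValueError("|r| must be <= 1")
        self.values = v


def _profiles(matrix: InnervationMatrix, axis: str) -> tuple[list[str], np.ndarray]:
    if axis == "rows":
        return list(matrix.rows), matrix.values.astype(float)
    if axis == "cols":
        return list(matrix.cols), matrix.values.T.astype(float)
    raise ValueError("axis must be 'rows' or 'cols'")


def _split_degenerate(labels: list[str], profs: np.ndarray):
    var = profs.var(axis=1)
    keep = var > 0
    excluded = [l for l, k in zip(labels, keep) if not k]
    return keep, excluded


def correlation_distance_matrix(
    matrix: InnervationMatrix, axis: str = "cols", degenerate: str = "exclude"
) -> DistanceMatrix:
    """Pairwise ``1 - r`` distances between row or column profiles.

    ``degenerate`` controls zero-variance profiles: ``exclude`` drops them
    (reported in ``.excluded``, with a warning), ``max`` keeps them at the
    maximal distance 2 from everything else.
    """
    labels, profs = _profiles(matrix, axis)
    keep, excluded = _split_degenerate(labels, profs)
    if degenerate == "exclude":
        if excluded:
            logger.warning("excluding zero-variance profiles: %s", excluded)
        labels = [l for l, k in zip(labels, keep) if k]
        profs = profs[keep]
    elif degenerate != "max":
        raise ValueError(f"unknown degenerate policy {degenerate!r}")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two non-degenerate profiles")
    d = np.zeros((n, n))
    variances = profs.var(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            if variances[i] == 0 or variances[j] == 0:
                d[i, j] = d[j, i] = 2.0
            else:
                d[i, j] = d[j, i] = 1.0 - pearson_correlation(profs[i], profs[j])
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, metric="correlation", excluded=excluded)


def autocorrelation(matrix: InnervationMatrix, axis: str = "cols") -> CorrelationMatrix:
    """Pairwise Pearson r between neuropil (cols) or DN (rows) profiles."""
    labels, profs = _profiles(matrix, axis)
    keep, excluded = _split_degenerate(labels, profs)
    if excluded:
        logger.warning("excluding zero-variance profiles: %s", excluded)
    labels = [l for l, k in zip(labels, keep) if k]
    profs = profs[keep]
    if len(labels) < 2:
        raise ValueError("need at least two non-degenerate profiles")
    n = len(labels)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r[i, j] = r[j, i] = pearson_correlation(profs[i], profs[j])
    return CorrelationMatrix(labels, r, excluded=excluded)


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    Leaves are numbered ``0..n-1`` in ``leaf_labels`` order; the cluster
    created by merge ``k`` has id ``n + k``.  ``merges`` lists
    ``(cluster_a, cluster_b, height, new_id)`` in merge order.
    """

    leaf_labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        n = len(self.leaf_labels)
        if len(self.merges) != n - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")
        heights = [m[2] for m in self.merges]
        if any(h2 < h1 - 1e-9 for h1, h2 in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def members(self, cluster_id: int) -> list[int]:
        """Leaf indices under a cluster id."""
        n = len(self.leaf_labels)
        if cluster_id < n:
            return [cluster_id]
        a, b, _, _ = self.merges[cluster_id - n]
        return self.members(a) + self.members(b)


def average_linkage(distance: DistanceMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    At every step the two clusters with minimal average pairwise
    dissimilarity merge at that average; ties go to the pair whose sorted
    (minimum-leaf-index) pair is lexicographically least, so output is
    deterministic across platforms.
    """
    n = len(distance)
    if n < 2:
        raise ValueError("need at least two items")
    d = {
        (i, j): float(distance.values[i, j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    minleaf = {i: i for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        best_key = None
        for (i, j), dij in d.items():
            key = (dij, tuple(sorted((minleaf[i], minleaf[j]))))
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
        i, j = best  # type: ignore[misc]
        h = d[(i, j)]
        new = next_id
        next_id += 1
        # Lance-Williams size-weighted update for average linkage
        for k in active:
            if k in (i, j):
                continue
            dik = d[tuple(sorted((i, k)))]
            djk = d[tuple(sorted((j, k)))]
            d[(k, new) if k < new else (new, k)] = (
                size[i] * dik + size[j] * djk
            ) / (size[i] + size[j])
        for pair in list(d):
            if i in pair or j in pair:
                del d[pair]
        active.discard(i)
        active.discard(j)
        active.add(new)
        size[new] = size[i] + size[j]
        minleaf[new] = min(minleaf[i], minleaf[j])
        merges.append((i, j, h, new))
    return Dendrogram(list(distance.labels), merges)


def cut_dendrogram(
    dendrogram: Dendrogram, k: int | None = None, h: float | None = None
) -> list[int]:
    """Flat cluster labels per leaf, cutting at ``k`` clusters or height ``h``.

    Labels are numbered 0, 1, ... by order of each cluster's first leaf.
    """
    n = len(dendrogram.leaf_labels)
    if (k is None) == (h is None):
        raise ValueError("give exactly one of k or h")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        n_merges = n - k
    else:
        if h < 0:
            raise ValueError("cut height must be nonnegative")
        n_merges = sum(1 for m in dendrogram.merges if m[2] <= h)
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _, new in dendrogram.merges[:n_merges]:
        parent[find(a)] = new
        parent[find(b)] = new
    roots: dict[int, int] = {}
    labels = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels.append(roots[r])
    return labels


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths equal to height differences."""
    n = len(dendrogram.leaf_labels)
    height = {i: 0.0 for i in range(n)}
    for a, b, h, new in dendrogram.merges:
        height[new] = h

    def render(cid: int, parent_h: float) -> str:
        bl = parent_h - height[cid]
        if cid < n:
            return f"{dendrogram.leaf_labels[cid]}:{bl:.6g}"
        a, b, h, _ = dendrogram.merges[cid - n]
        return f"({render(a, h)},{render(b, h)}):{bl:.6g}"

    root = dendrogram.merges[-1][3]
    a, b, h, _ = dendrogram.merges[-1]
    return f"({render(a, h)},{render(b, h)});"
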