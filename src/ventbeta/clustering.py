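"""UPGMA (average-linkage) clustering of sites from a dissimilarity matrix.

UPGMA merges, at each step, the pair of clusters with the smallest average
inter-cluster dissimilarity; the merge height equals that average, so the
result is ultrametric.  Ties on the minimum are broken towards the
lowest-index pair, making the dendrogram deterministic.  Newick export
assigns each leaf-to-node branch half the merge height (the ultrametric
depth), so root-to-leaf path lengths are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .incidence import IncidenceMatrix
from .partition import beta_j_matrix

__all__ = ["Dendrogram", "upgma", "upgma_from_incidence", "to_newick"]


@dataclass(frozen=True)
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges[k] = (p, q)`` joins cluster indices p and q (indices < n are
    leaves, n + k refers to the cluster created at step k) at height
    ``heights[k]``.
    """

    leaf_labels: tuple[str, ...]
    merges: tuple[tuple[int, int], ...]
    heights: tuple[float, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def cophenetic(self) -> np.ndarray:
        """Pairwise cophenetic distances (merge height joining each pair)."""
        n = self.n_leaves
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        C = np.zeros((n, n))
        for k, ((p, q), h) in enumerate(zip(self.merges, self.heights)):
            for i in members[p]:
                for j in members[q]:
                    C[i, j] = C[j, i] = h
            members[n + k] = members.pop(p) + members.pop(q)
        return C


def upgma(D: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """Average-linkage clustering of a symmetric dissimilarity matrix.

    Cluster-to-cluster distances are size-weighted averages of the original
    leaf-to-leaf dissimilarities (true UPGMA).  Requires a symmetric matrix
    with a zero diagonal and at least two items.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError(f"matrix shape {D.shape} does not match {n} labels")
    if n < 2:
        raise ValueError("need at least 2 items")
    if not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("dissimilarity matrix must have a zero diagonal")

    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int]] = []
    heights: list[float] = []

    for step in range(n - 1):
        # lowest-index pair wins ties on the minimum distance
        best = None
        for ai, p in enumerate(active):
            for q in active[ai + 1 :]:
                d = dist[(p, q) if p < q else (q, p)]
                if best is None or d < best[0] - 1e-15:
                    best = (d, p, q)
        d, p, q = best
        new = n + step
        merges.append((p, q))
        heights.append(d)
        sp, sq = size[p], size[q]
        size[new] = sp + sq
        for r in active:
            if r in (p, q):
                continue
            dpr = dist[(p, r) if p < r else (r, p)]
            dqr = dist[(q, r) if q < r else (r, q)]
            dist[(r, new)] = (sp * dpr + sq * dqr) / (sp + sq)
        active = [r for r in active if r not in (p, q)] + [new]

    return Dendrogram(tuple(str(l) for l in labels), tuple(merges), tuple(heights))


def upgma_from_incidence(matrix: IncidenceMatrix) -> Dendrogram:
    """UPGMA dendrogram of sites from their pairwise beta_J dissimilarities."""
    D = beta_j_matrix(matrix)
    return upgma(D.to_numpy(), matrix.site_ids)


def to_newick(tree: Dendrogram, digits: int = 6) -> str:
    """Newick string with ultrametric branch lengths (leaf depth = height/2)."""
    n = tree.n_leaves
    depth: dict[int, float] = {i: 0.0 for i in range(n)}
    text: dict[int, str] = {
        i: _escape(lbl) for i, lbl in enumerate(tree.leaf_labels)
    }
    for k, ((p, q), h) in enumerate(zip(tree.merges, tree.heights)):
        node_depth = h / 2
        bp = node_depth - depth[p]
        bq = node_depth - depth[q]
        text[n + k] = (
            f"({text[p]}:{bp:.{digits}f},{text[q]}:{bq:.{digits}f})"
        )
        depth[n + k] = node_depth
    return text[n + len(tree.merges) - 1] + ";"


def _escape(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label
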