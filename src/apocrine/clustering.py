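"""Agglomerative hierarchical clustering on 1 - Pearson dissimilarity.

Ward's linkage is applied through the Lance-Williams recurrence directly to
the dissimilarity matrix as supplied (the historical ``ward.D`` dialect):

    d(k, i+j) = [(n_i + n_k) d(k,i) + (n_j + n_k) d(k,j) - n_k d(i,j)]
                / (n_i + n_j + n_k)

A squared-dissimilarity variant (``ward.D2`` semantics) is available via
``squared=True``. Merge ties are broken by the lowest pair index, which
makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy import stats

from .io import DataError, ExpressionMatrix

__all__ = [
    "Dendrogram",
    "correlation_distance",
    "ward_cluster",
    "cut_dendrogram",
    "cluster_class_association",
]


@dataclass
class Dendrogram:
    """Merge history for n leaves: n-1 merges with non-decreasing heights.

    ``linkage`` follows the scipy convention (leaf clusters 0..n-1, the
    cluster created at step k is n+k).
    """

    linkage: np.ndarray
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise DataError(f"linkage shape {self.linkage.shape} invalid for {n} leaves")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise DataError("merge heights must be non-decreasing under Ward")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def merges(self) -> list[tuple[int, int]]:
        return [(int(a), int(b)) for a, b in self.linkage[:, :2]]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.leaf_ids[i] for i in order]

    def to_newick(self) -> str:
        n = self.n_leaves
        rep: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        prev = {i: 0.0 for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - prev[a]
            lb = h - prev[b]
            rep[n + step] = f"({rep[a]}:{la:g},{rep[b]}:{lb:g})"
            prev[n + step] = h
        return rep[n + self.n_leaves - 2] + ";"


def correlation_distance(X: ExpressionMatrix, axis: str = "samples") -> np.ndarray:
    """Pairwise 1 - Pearson correlation between samples (columns) or genes
    (rows). The result is symmetric with zero diagonal, in [0, 2]."""
    if axis not in ("samples", "genes"):
        raise DataError(f"axis must be 'samples' or 'genes', got {axis!r}")
    M = X.values.T if axis == "samples" else X.values
    ids = X.sample_ids if axis == "samples" else X.probe_ids
    if M.shape[0] < 2:
        raise DataError(f"need >= 2 {axis} to compute distances")
    sd = M.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DataError(f"zero-variance {axis[:-1]} vector: {ids[zero[0]]!r}")
    r = np.corrcoef(M)
    D = 1.0 - r
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def ward_cluster(
    D: np.ndarray, leaf_ids: list[str] | None = None, squared: bool = False
) -> Dendrogram:
    """Ward agglomeration of a dissimilarity matrix via the Lance-Williams
    recurrence applied to D as given (or to D**2 when ``squared``)."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DataError(f"dissimilarity matrix must be square, got {D.shape}")
    if not np.allclose(D, D.T, atol=1e-8):
        raise DataError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise DataError("leaf_ids length must match matrix size")

    C = D.astype(float).copy()
    if squared:
        C = C**2
    np.fill_diagonal(C, np.inf)
    sizes = np.ones(n)
    cluster_id = np.arange(n)  # scipy-style id of the cluster living in each slot
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        M = np.where(active[:, None] & active[None, :], C, np.inf)
        # lowest pair index on ties: argmin of row-major flattened matrix
        flat = int(np.argmin(M))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = C[i, j]
        ni, nj = sizes[i], sizes[j]
        a, b = cluster_id[i], cluster_id[j]
        if a > b:
            a, b = b, a
        Z[step] = [a, b, np.sqrt(max(h, 0.0)) if squared else h, ni + nj]

        k = active.copy()
        k[i] = k[j] = False
        nk = sizes[k]
        C[i, k] = C[k, i] = ((ni + nk) * C[i, k] + (nj + nk) * C[j, k] - nk * h) / (
            ni + nj + nk
        )
        sizes[i] = ni + nj
        active[j] = False
        cluster_id[i] = n + step
        C[j, :] = C[:, j] = np.inf

    return Dendrogram(linkage=Z, leaf_ids=list(leaf_ids))


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Labels induced by removing the k-1 highest merges; clusters are
    numbered 0..k-1 by the index of their first leaf."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    for lab in raw:  # first-leaf-index order
        if lab not in relabel:
            relabel[lab] = len(relabel)
    return {leaf: relabel[lab] for leaf, lab in zip(dendrogram.leaf_ids, raw)}


def cluster_class_association(labels, classes) -> tuple[float, float, str]:
    """Chi-square test of independence between two categorical vectors,
    replaced by the two-sided Fisher exact test for 2x2 tables whose
    expected counts are not all above 5. Returns (statistic, p, test_used)."""
    labels = np.asarray(labels)
    classes = np.asarray(classes)
    if labels.shape != classes.shape:
        raise DataError("label vectors must have equal length")
    lab_levels = np.unique(labels)
    cls_levels = np.unique(classes)
    if len(lab_levels) < 2 or len(cls_levels) < 2:
        raise DataError("association test needs >= 2 categories on each side")
    table = np.zeros((len(lab_levels), len(cls_levels)), dtype=int)
    for i, l in enumerate(lab_levels):
        for j, c in enumerate(cls_levels):
            table[i, j] = int(np.sum((labels == l) & (classes == c)))
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if table.shape == (2, 2) and (expected <= 5).any():
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher"
    return float(chi2), float(p), "chi-square"
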