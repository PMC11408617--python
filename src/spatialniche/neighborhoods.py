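"""Per-cell k-nearest-neighbor construction and neighborhood composition.

Neighbor search runs independently within each sample on Euclidean pixel
distances, so cross-sample neighbors never occur. The neighbor list of a
cell excludes the cell itself and is sorted by ascending distance with ties
broken by ascending row position in the cell table — the ordering is exact
and deterministic, matching a brute-force all-pairs oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .config import TypeVocabulary
from .io import CellTable


@dataclass
class NeighborIndex:
    """k nearest same-sample cells per cell.

    ``neighbors`` and ``distances`` are (n_cells, k) arrays aligned with the
    originating cell table's row order; neighbor entries are global row
    positions in that table.
    """

    neighbors: np.ndarray   # (n, k) int row positions
    distances: np.ndarray   # (n, k) float pixel distances
    k: int
    sample_of: np.ndarray   # (n,) sample id per row, for validation

    def __post_init__(self):
        n = len(self.neighbors)
        if self.neighbors.shape != (n, self.k) or self.distances.shape != (n, self.k):
            raise ValueError(
                f"expected exactly k={self.k} entries per cell, got shape "
                f"{self.neighbors.shape}")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise ValueError("neighbor lists must be sorted by ascending distance")
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise ValueError("a cell may not be its own neighbor")


def _exact_knn_rows(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact k-NN with (distance, index) ordering for one point set.

    KD-tree candidates are re-sorted by exact squared distance with stable
    index tie-breaks; rows whose cut falls inside a tie group are resolved
    by a radius query over the full tie set.
    """
    n = len(coords)
    m = min(n, k + 2)  # +1 for self, +1 to detect a tie at the cut
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=m)
    if m == 1:
        idx = idx[:, None]

    diff = coords[idx] - coords[:, None, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    # push self to the end so the k nearest others come first
    self_mask = idx == np.arange(n)[:, None]
    d2 = np.where(self_mask, np.inf, d2)
    # order each row by (d2, index): stable argsort on index first, then d2
    o1 = np.argsort(idx, axis=1, kind="stable")
    idx = np.take_along_axis(idx, o1, axis=1)
    d2 = np.take_along_axis(d2, o1, axis=1)
    o2 = np.argsort(d2, axis=1, kind="stable")
    idx = np.take_along_axis(idx, o2, axis=1)
    d2 = np.take_along_axis(d2, o2, axis=1)

    nbr = idx[:, :k].copy()
    dist2 = d2[:, :k].copy()

    # rows needing a rescan: self missing from the candidate window, or a
    # distance tie straddling the cut between ranks k-1 and k
    missing_self = ~self_mask.any(axis=1)
    tie_at_cut = np.zeros(n, dtype=bool)
    if d2.shape[1] > k:
        tie_at_cut = d2[:, k - 1] == d2[:, k]
    for i in np.flatnonzero(missing_self | tie_at_cut):
        radius = float(np.sqrt(dist2[i, k - 1])) * (1 + 1e-12) + 1e-300
        cand = np.array(tree.query_ball_point(coords[i], radius))
        cand = cand[cand != i]
        cd = coords[cand] - coords[i]
        cd2 = np.einsum("ij,ij->i", cd, cd)
        order = np.lexsort((cand, cd2))
        if len(order) < k:  # radius fell short numerically; widen until enough
            radius = float(np.sqrt(d2[i, min(k + 1, d2.shape[1] - 1)])) * 1.01
            while True:
                cand = np.array(tree.query_ball_point(coords[i], radius))
                cand = cand[cand != i]
                if len(cand) >= k:
                    break
                radius *= 2.0
            cd = coords[cand] - coords[i]
            cd2 = np.einsum("ij,ij->i", cd, cd)
            order = np.lexsort((cand, cd2))
        nbr[i] = cand[order[:k]]
        dist2[i] = cd2[order[:k]]
    return nbr, np.sqrt(dist2)


def knn_neighbors(cells: CellTable, k: int) -> NeighborIndex:
    """Find each cell's k nearest same-sample cells (self excluded).

    Raises if any sample holds fewer than k+1 cells.
    """
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    n = len(cells)
    neighbors = np.empty((n, k), dtype=np.intp)
    distances = np.empty((n, k), dtype=float)
    sample_ids = cells.frame["sample_id"].to_numpy()
    coords = cells.coordinates()
    for sid in cells.samples:
        rows = np.flatnonzero(sample_ids == sid)
        if len(rows) <= k:
            raise ValueError(
                f"sample {sid!r} has {len(rows)} cells; need more than k={k}")
        nbr, dist = _exact_knn_rows(coords[rows], k)
        neighbors[rows] = rows[nbr]
        distances[rows] = dist
    return NeighborIndex(neighbors, distances, k, sample_ids)


@dataclass
class NeighborhoodComposition:
    """Cell-type proportion vector per neighborhood.

    ``proportions`` is (n_cells, n_types) in vocabulary order; each row is
    non-negative and sums to 1. ``include_self`` records whether the index
    cell itself was counted (window of k+1 cells) or not (k cells).
    """

    proportions: np.ndarray
    vocabulary: TypeVocabulary
    k: int
    include_self: bool
    sample_of: np.ndarray

    def __post_init__(self):
        if self.proportions.shape[1] != len(self.vocabulary):
            raise ValueError("composition width must equal vocabulary size")
        if (self.proportions < 0).any():
            raise ValueError("proportions must be non-negative")
        sums = self.proportions.sum(axis=1)
        if len(sums) and np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("composition rows must sum to 1")


def composition_vectors(index: NeighborIndex, cells: CellTable,
                        vocabulary: TypeVocabulary,
                        include_self: bool = True) -> NeighborhoodComposition:
    """Summarize each neighborhood as type proportions over the vocabulary.

    With ``include_self`` the window holds k+1 cells (the cell plus its k
    nearest neighbors), otherwise the k neighbors alone.
    """
    if len(index.neighbors) != len(cells):
        raise ValueError("index and cell table differ in length")
    codes = cells.type_codes(vocabulary)
    n, t = len(cells), len(vocabulary)
    counts = np.zeros((n, t), dtype=float)
    neighbor_codes = codes[index.neighbors]  # (n, k)
    for j in range(t):
        counts[:, j] = (neighbor_codes == j).sum(axis=1)
    if include_self:
        counts[np.arange(n), codes] += 1
    denom = index.k + (1 if include_self else 0)
    return NeighborhoodComposition(counts / denom, vocabulary, index.k,
                                   include_self, index.sample_of)
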