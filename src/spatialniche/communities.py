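"""Micro-clustering of neighborhood compositions, merging into spatial
communities, and cell-type enrichment scoring.

Clustering is run independently per sample (k-means on raw proportion
vectors, squared-Euclidean objective, seeded best-of-restarts). Micro-
clusters are merged into communities either by a user-supplied map or by
average-linkage agglomeration of centroid compositions under correlation
distance. The enrichment score of type t in community c is
p(t | c) / p(t), so 1 means no enrichment and the cell-count-weighted mean
over communities is exactly 1 for every type present in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .config import TypeVocabulary
from .io import CellTable
from .neighborhoods import NeighborhoodComposition


@dataclass
class MicroClusterAssignment:
    """Per-cell micro-cluster ids (1..K per sample) with centroids."""

    labels: np.ndarray                      # (n_cells,) ints in 1..K
    centroids: dict[str, np.ndarray]        # sample -> (K, n_types)
    K: int
    seed: int
    n_restarts: int
    sample_of: np.ndarray

    def __post_init__(self):
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.K:
            raise ValueError("micro-cluster ids must lie in 1..K")
        for sid, c in self.centroids.items():
            if (c < -1e-9).any() or np.abs(c.sum(axis=1) - 1.0).max() > 1e-6:
                raise ValueError(
                    f"sample {sid!r}: centroids are not composition vectors")


@dataclass
class EnrichmentMatrix:
    """Per sample: community x cell-type enrichment scores E >= 0."""

    scores: dict[str, pd.DataFrame]          # sample -> (clusters x types)
    cluster_sizes: dict[str, pd.Series]      # sample -> cells per cluster

    def check_weighted_mean(self, atol: float = 1e-9) -> None:
        """Count-weighted mean of E(., t) over clusters must be 1 for every
        type present in the sample."""
        for sid, df in self.scores.items():
            sizes = self.cluster_sizes[sid].reindex(df.index).to_numpy(dtype=float)
            w = sizes / sizes.sum()
            means = w @ df.to_numpy()
            present = df.to_numpy().sum(axis=0) > 0
            if np.abs(means[present] - 1.0).max(initial=0.0) > atol:
                raise AssertionError(f"weighted-mean invariant violated in {sid!r}")


@dataclass
class CommunityAssignment:
    """Per-cell community label plus the micro-cluster merge map."""

    labels: np.ndarray                       # (n_cells,) community names
    merge_map: dict[str, dict[int, str]]     # sample -> micro-cluster -> community
    sample_of: np.ndarray


def cluster_compositions(comp: NeighborhoodComposition, K: int,
                         seed: int = 0, n_restarts: int = 10,
                         standardize: bool = False) -> MicroClusterAssignment:
    """Seeded per-sample k-means over neighborhood composition vectors.

    ``standardize`` (off by default) z-scores composition columns before
    clustering; the default clusters raw proportions.
    """
    if K < 1:
        raise ValueError("K must be a positive integer")
    n = len(comp.proportions)
    labels = np.zeros(n, dtype=np.intp)
    centroids: dict[str, np.ndarray] = {}
    for sid in dict.fromkeys(comp.sample_of):
        rows = np.flatnonzero(comp.sample_of == sid)
        if len(rows) < K:
            raise ValueError(
                f"sample {sid!r} has {len(rows)} cells, fewer than K={K}")
        x = comp.proportions[rows]
        fit_x = x
        if standardize:
            sd = x.std(axis=0)
            fit_x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed).fit(fit_x)
        labels[rows] = km.labels_ + 1
        # centroids reported in composition space regardless of standardization
        cent = np.vstack([x[km.labels_ == j].mean(axis=0) for j in range(K)])
        centroids[sid] = cent
    return MicroClusterAssignment(labels, centroids, K, seed, n_restarts,
                                  comp.sample_of.copy())


def enrichment_scores(labels: np.ndarray, cells: CellTable,
                      vocabulary: TypeVocabulary) -> EnrichmentMatrix:
    """E(c, t) = p(t | c) / p(t) per sample; 0/0 := 0 for absent types.

    Empty clusters never appear (labels are taken as observed); any label
    value is accepted, so this works for micro-clusters and for merged
    communities alike.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cells):
        raise ValueError("assignment must cover every cell")
    codes = cells.type_codes(vocabulary)
    sample_ids = cells.frame["sample_id"].to_numpy()
    t = len(vocabulary)
    scores: dict[str, pd.DataFrame] = {}
    sizes: dict[str, pd.Series] = {}
    for sid in cells.samples:
        rows = np.flatnonzero(sample_ids == sid)
        global_counts = np.bincount(codes[rows], minlength=t).astype(float)
        global_prop = global_counts / len(rows)
        uniq = pd.unique(labels[rows])
        mat = np.zeros((len(uniq), t))
        n_per = np.zeros(len(uniq), dtype=int)
        for i, c in enumerate(uniq):
            members = rows[labels[rows] == c]
            n_per[i] = len(members)
            prop = np.bincount(codes[members], minlength=t) / len(members)
            with np.errstate(invalid="ignore", divide="ignore"):
                e = prop / global_prop
            mat[i] = np.where(global_prop > 0, e, 0.0)
        order = np.argsort([str(u) for u in uniq])
        scores[sid] = pd.DataFrame(mat[order], index=pd.Index(uniq[order], name="cluster"),
                                   columns=list(vocabulary.names))
        sizes[sid] = pd.Series(n_per[order], index=scores[sid].index, name="n_cells")
    return EnrichmentMatrix(scores, sizes)


def _centroid_distances(centroids: np.ndarray) -> np.ndarray:
    """Correlation distance between centroid rows, defined for constant rows:
    identical rows get 0, a constant vs non-constant row gets 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        d = pdist(centroids, metric="correlation")
    d = np.clip(d, 0.0, None)
    if np.isnan(d).any():
        sq = squareform(d)
        const = centroids.std(axis=1) == 0
        for i in np.flatnonzero(const):
            for j in range(len(centroids)):
                if i == j:
                    continue
                if np.isnan(sq[i, j]):
                    sq[i, j] = sq[j, i] = (
                        0.0 if np.array_equal(centroids[i], centroids[j]) else 1.0)
        d = squareform(sq, checks=False)
    return d


def merge_microclusters(assignment: MicroClusterAssignment,
                        enrichment: EnrichmentMatrix,
                        *,
                        manual_map: dict[str, dict[int, str]] | None = None,
                        n_communities: int | None = None,
                        ) -> CommunityAssignment:
    """Merge micro-clusters into spatial communities.

    Exactly one strategy applies: a ``manual_map`` (sample -> micro-cluster
    id -> community name, total and surjective) is applied verbatim;
    otherwise micro-cluster centroids are agglomerated (average linkage,
    correlation distance) and the dendrogram cut at ``n_communities``.
    Merging only coarsens the micro-cluster partition.
    """
    if (manual_map is None) == (n_communities is None):
        raise ValueError("provide exactly one of manual_map or n_communities")
    K = assignment.K
    merge_map: dict[str, dict[int, str]] = {}
    labels = np.empty(len(assignment.labels), dtype=object)
    for sid, cent in assignment.centroids.items():
        if manual_map is not None:
            if sid not in manual_map:
                raise ValueError(f"manual map missing sample {sid!r}")
            mapping = {int(k): str(v) for k, v in manual_map[sid].items()}
            missing = set(range(1, K + 1)) - set(mapping)
            if missing:
                raise ValueError(
                    f"manual map for {sid!r} is not total; missing {sorted(missing)}")
        else:
            if not 2 <= n_communities <= K:
                raise ValueError(
                    f"n_communities must lie in [2, K={K}], got {n_communities}")
            z = linkage(_centroid_distances(cent), method="average")
            flat = fcluster(z, t=n_communities, criterion="maxclust")
            mapping = {mc + 1: f"C{flat[mc]}" for mc in range(K)}
        merge_map[sid] = mapping
        rows = np.flatnonzero(assignment.sample_of == sid)
        for mc, comm in mapping.items():
            labels[rows[assignment.labels[rows] == mc]] = comm
    return CommunityAssignment(labels, merge_map, assignment.sample_of.copy())


def name_communities(enrichment: EnrichmentMatrix, *, m: int = 2,
                     threshold: float = 1.5) -> dict[str, dict]:
    """Name each community after its up-to-m most enriched types.

    Types with E >= threshold, ordered by E descending (ties by vocabulary
    order), joined with "/"; "Mixed" if none pass.
    """
    names: dict[str, dict] = {}
    for sid, df in enrichment.scores.items():
        per_sample = {}
        for cluster, row in df.iterrows():
            passing = row[row >= threshold]
            if passing.empty:
                per_sample[cluster] = "Mixed"
            else:
                top = passing.sort_values(ascending=False, kind="stable").index[:m]
                per_sample[cluster] = "/".join(top)
        names[sid] = per_sample
    return names
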