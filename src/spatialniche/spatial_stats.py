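"""Nearest-cell-type distance analysis, community composition summaries,
and the rank-based group comparison."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial import cKDTree

from .config import TypeVocabulary
from .io import CellTable, UNKNOWN_LABEL


def nearest_type_distance(cells: CellTable,
                          query: Sequence[str] | np.ndarray,
                          target_types: Sequence[str],
                          px_per_um: float = 2.65,
                          exclude_unknown_targets: bool = True,
                          ) -> pd.DataFrame:
    """Shortest Euclidean distance from each query cell to each target type.

    ``query`` is either a list of cell types (cells of those types are the
    queries, grouped by their own type) or an array of per-cell group labels
    aligned with the table (cells labeled None/NaN are skipped). Distances
    are computed within each sample; a query cell of the target type never
    matches itself. Micrometer values are the pixel distance divided by
    ``px_per_um`` — a single division, no re-rounding.

    Returns a table with columns ``sample_id, cell_id, query_group,
    target_type, distance_px, distance_um``; a (sample, target) pair with no
    target cells yields NaN distances and a warning.
    """
    if not px_per_um > 0:
        raise ValueError(f"px_per_um must be > 0, got {px_per_um}")
    frame = cells.frame
    types = frame["cell_type"].to_numpy()
    if isinstance(query, (list, tuple)) and all(isinstance(q, str) for q in query):
        groups = np.where(np.isin(types, list(query)), types, None)
    else:
        groups = np.asarray(query, dtype=object)
        if len(groups) != len(cells):
            raise ValueError("per-cell query labels must cover the table")
    if exclude_unknown_targets and UNKNOWN_LABEL in target_types:
        raise ValueError(f"{UNKNOWN_LABEL!r} targets are excluded by default; "
                         "pass exclude_unknown_targets=False to allow them")

    coords = cells.coordinates()
    sample_ids = frame["sample_id"].to_numpy()
    records = []
    for sid in cells.samples:
        in_sample = sample_ids == sid
        q_rows = np.flatnonzero(in_sample & pd.notna(groups))
        if len(q_rows) == 0:
            continue
        for target in target_types:
            t_rows = np.flatnonzero(in_sample & (types == target))
            d_px = _min_distances(coords, q_rows, t_rows)
            if d_px is None:
                warnings.warn(f"sample {sid!r} has no {target!r} cells; "
                              "emitting missing distances")
                d_px = np.full(len(q_rows), np.nan)
            for r, d in zip(q_rows, d_px):
                records.append((sid, frame["cell_id"].iat[r], groups[r],
                                target, d, d / px_per_um))
    return pd.DataFrame(records, columns=["sample_id", "cell_id", "query_group",
                                          "target_type", "distance_px",
                                          "distance_um"])


def _min_distances(coords: np.ndarray, q_rows: np.ndarray,
                   t_rows: np.ndarray) -> np.ndarray | None:
    """Min distance from each query row to the target rows, self excluded."""
    if len(t_rows) == 0:
        return None
    tree = cKDTree(coords[t_rows])
    t_pos = {row: i for i, row in enumerate(t_rows)}
    is_target = np.array([r in t_pos for r in q_rows])
    out = np.empty(len(q_rows))
    plain = ~is_target
    if plain.any():
        out[plain], _ = tree.query(coords[q_rows[plain]], k=1)
    for i in np.flatnonzero(is_target):
        if len(t_rows) == 1:
            out[i] = np.nan  # the query is the sole target cell
            continue
        d, j = tree.query(coords[q_rows[i]], k=2)
        out[i] = d[1] if t_rows[j[0]] == q_rows[i] else d[0]
    if np.isnan(out).all():
        return None
    return out


def summarize_distances(table: pd.DataFrame, *, n_bins: int = 50,
                        max_um: float | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled-across-samples summaries per (query group, target type).

    Returns ``(summary, density)``: per-group n / mean / median in um, and
    histogram counts over shared bins (common across groups for overlay).
    """
    if table.empty:
        raise ValueError("distance table is empty")
    valid = table.dropna(subset=["distance_um"])
    if max_um is None:
        max_um = float(valid["distance_um"].max()) if len(valid) else 1.0
    edges = np.linspace(0.0, max_um if max_um > 0 else 1.0, n_bins + 1)
    summaries, densities = [], []
    for (group, target), sub in valid.groupby(["query_group", "target_type"],
                                              sort=True):
        d = sub["distance_um"].to_numpy()
        summaries.append((group, target, len(d), d.mean(), np.median(d)))
        counts, _ = np.histogram(d, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            densities.append((group, target, lo, hi, int(c)))
    summary = pd.DataFrame(summaries, columns=["query_group", "target_type",
                                               "n", "mean_um", "median_um"])
    density = pd.DataFrame(densities, columns=["query_group", "target_type",
                                               "bin_lo_um", "bin_hi_um", "count"])
    return summary, density


def community_type_proportions(labels: np.ndarray, cells: CellTable,
                               vocabulary: TypeVocabulary,
                               focus_types: Sequence[str] | None = None
                               ) -> pd.DataFrame:
    """Percent of each cell type among each community's cells, per sample.

    Rows are (sample_id, community); columns are cell types in vocabulary
    order. Over the full vocabulary each row sums to 100; ``focus_types``
    subsets the columns afterwards (subset rows need not sum to 100).
    """
    labels = np.asarray(labels)
    if len(labels) != len(cells):
        raise ValueError("assignment must cover every cell")
    codes = cells.type_codes(vocabulary)
    sample_ids = cells.frame["sample_id"].to_numpy()
    rows = []
    index = []
    for sid in cells.samples:
        in_sample = sample_ids == sid
        for comm in sorted(set(map(str, labels[in_sample]))):
            members = in_sample & (labels.astype(str) == comm)
            counts = np.bincount(codes[members], minlength=len(vocabulary))
            rows.append(100.0 * counts / counts.sum())
            index.append((sid, comm))
    out = pd.DataFrame(rows, columns=list(vocabulary.names),
                       index=pd.MultiIndex.from_tuples(index,
                                                       names=["sample_id",
                                                              "community"]))
    if focus_types is not None:
        out = out[list(focus_types)]
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-squared(g-1).

    All values identical across all groups is defined as (H=0, p=1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)
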