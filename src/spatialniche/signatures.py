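"""Gene-signature module scoring with expression-bin-matched control genes,
and the top-percentile spatial quantification.

The score of a spot is the mean normalized expression of the signature
genes minus the mean over a pooled control set: genes are ranked by mean
expression across spots, cut into equal-frequency bins, and each signature
gene contributes control genes drawn from its own bin. A score of 0 means
"no different from expression-matched background".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import SpotMatrix


def normalize_log(matrix: SpotMatrix, scale_total: float = 1e4) -> np.ndarray:
    """Library-size normalization to ``scale_total`` per spot, then log1p.

    Spots with zero total get an all-zero row and a warning.
    """
    counts = matrix.counts.astype(float)
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} spots have zero total counts; "
                      "their normalized rows are zero")
    safe = np.where(zero, 1.0, totals)
    return np.log1p(counts * (scale_total / safe)[:, None])


@dataclass
class SignatureScoreVector:
    """Per-spot module score with the metadata needed to reproduce it."""

    scores: np.ndarray
    signature: list[str]
    n_bins: int
    n_ctrl: int
    seed: int
    normalization: str = "log1p_cp10k"


def _expression_bins(mean_expr: np.ndarray, genes: list[str],
                     n_bins: int) -> np.ndarray:
    """Equal-frequency bin id per gene, ranking by (mean, name) so the
    binning is invariant to gene order in the matrix."""
    name_rank = np.argsort(np.argsort(np.array(genes)))
    order = np.lexsort((name_rank, mean_expr))
    ranks = np.empty(len(genes), dtype=np.intp)
    ranks[order] = np.arange(len(genes))
    return (ranks * n_bins) // len(genes)


def module_score(expr: np.ndarray, genes: list[str], signature: list[str],
                 *, n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> SignatureScoreVector:
    """Bin-matched control-gene module score per spot.

    ``expr`` is a (spots x genes) normalized matrix whose columns follow
    ``genes``. For each signature gene, ``n_ctrl`` control genes are drawn
    (seeded, without replacement, signature genes excluded) from the gene's
    expression bin; the pooled control set is deduplicated. The score is
    mean(signature columns) - mean(pooled control columns) per spot.

    Signature genes missing from the matrix are dropped with a warning
    (error if none remain); a bin with fewer than ``n_ctrl`` eligible
    controls is sampled with replacement (then deduplicated) with a warning.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    if len(genes) != expr.shape[1]:
        raise ValueError("gene list must match matrix width")
    col = {g: i for i, g in enumerate(genes)}
    present = [g for g in signature if g in col]
    missing = [g for g in signature if g not in col]
    if missing:
        if not present:
            raise ValueError("no signature gene is present in the matrix")
        warnings.warn(f"dropping {len(missing)} signature genes absent from "
                      f"the matrix: {missing[:5]}...")
    sig_set = set(present)

    mean_expr = expr.mean(axis=0)
    bins = _expression_bins(mean_expr, genes, n_bins)

    rng = np.random.default_rng(seed)
    controls: set[str] = set()
    # iterate signature genes in sorted order so draws do not depend on the
    # caller's gene-list ordering
    for g in sorted(present):
        pool = sorted(gene for gene in np.array(genes)[bins == bins[col[g]]]
                      if gene not in sig_set)
        if not pool:
            warnings.warn(f"no eligible control genes in the bin of {g!r}")
            continue
        if len(pool) < n_ctrl:
            warnings.warn(f"bin of {g!r} holds {len(pool)} eligible controls "
                          f"(< n_ctrl={n_ctrl}); sampling with replacement")
            draw = rng.choice(pool, size=n_ctrl, replace=True)
        else:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        controls.update(draw.tolist())
    if not controls:
        raise ValueError("control pool is empty")

    sig_cols = [col[g] for g in present]
    ctrl_cols = [col[g] for g in sorted(controls)]
    scores = expr[:, sig_cols].mean(axis=1) - expr[:, ctrl_cols].mean(axis=1)
    return SignatureScoreVector(scores, list(present), n_bins, n_ctrl, seed)


def high_fraction_by_cluster(scores: np.ndarray, clusters: np.ndarray,
                             top_pct: float = 10.0) -> dict:
    """Percent of spots per cluster at or above the global top-percentile cut.

    The threshold is the (100 - top_pct) percentile of all scores (linear
    interpolation); spots with score >= threshold are flagged, so fully tied
    scores flag every spot (documented tie convention). Returns
    ``{cluster: percent}`` plus the threshold under key ``"_threshold"``.
    """
    scores = np.asarray(scores, dtype=float)
    clusters = np.asarray(clusters)
    if len(scores) != len(clusters):
        raise ValueError("cluster labels must cover all scored spots")
    if not 0 < top_pct < 100:
        raise ValueError("top_pct must lie in (0, 100)")
    threshold = float(np.percentile(scores, 100.0 - top_pct))
    flagged = scores >= threshold
    out: dict = {}
    for c in sorted(set(map(str, clusters))):
        members = clusters.astype(str) == c
        if not members.any():
            warnings.warn(f"cluster {c!r} is empty; omitted")
            continue
        out[c] = 100.0 * flagged[members].sum() / members.sum()
    out["_threshold"] = threshold
    return out
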