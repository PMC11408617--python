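"""Synthetic tissue and spot-matrix generators with planted spatial niches.

Cells are placed by independent homogeneous Poisson processes, one per
region, with later regions overriding earlier ones where they overlap (an
overridden region's cells are removed there, so the topmost region's density
and mixture govern each location). Each region draws one realized type
mixture from its Dirichlet concentration vector, and cell types are i.i.d.
from that mixture. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_VOCABULARY, TypeVocabulary
from .io import CellTable, SpotMatrix


# ---------------------------------------------------------------------------
# Region geometry

@dataclass(frozen=True)
class Background:
    """Covers the whole canvas."""

    def contains(self, xy: np.ndarray, canvas: tuple[float, float]) -> np.ndarray:
        return np.ones(len(xy), dtype=bool)

    def area(self, canvas: tuple[float, float]) -> float:
        return canvas[0] * canvas[1]

    def sample(self, n: int, canvas, rng) -> np.ndarray:
        return rng.uniform((0.0, 0.0), canvas, size=(n, 2))

    def within_canvas(self, canvas) -> bool:
        return True


@dataclass(frozen=True)
class Disk:
    cx: float
    cy: float
    r: float

    def contains(self, xy, canvas):
        return (xy[:, 0] - self.cx) ** 2 + (xy[:, 1] - self.cy) ** 2 <= self.r ** 2

    def area(self, canvas):
        return math.pi * self.r ** 2

    def sample(self, n, canvas, rng):
        # uniform on disk via polar inversion
        u = rng.uniform(size=n)
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        rr = self.r * np.sqrt(u)
        return np.column_stack([self.cx + rr * np.cos(theta),
                                self.cy + rr * np.sin(theta)])

    def within_canvas(self, canvas):
        return (self.cx - self.r >= 0 and self.cy - self.r >= 0
                and self.cx + self.r <= canvas[0] and self.cy + self.r <= canvas[1])


@dataclass(frozen=True)
class Annulus:
    cx: float
    cy: float
    r_inner: float
    r_outer: float

    def contains(self, xy, canvas):
        d2 = (xy[:, 0] - self.cx) ** 2 + (xy[:, 1] - self.cy) ** 2
        return (d2 >= self.r_inner ** 2) & (d2 <= self.r_outer ** 2)

    def area(self, canvas):
        return math.pi * (self.r_outer ** 2 - self.r_inner ** 2)

    def sample(self, n, canvas, rng):
        u = rng.uniform(self.r_inner ** 2, self.r_outer ** 2, size=n)
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
        rr = np.sqrt(u)
        return np.column_stack([self.cx + rr * np.cos(theta),
                                self.cy + rr * np.sin(theta)])

    def within_canvas(self, canvas):
        return (self.cx - self.r_outer >= 0 and self.cy - self.r_outer >= 0
                and self.cx + self.r_outer <= canvas[0]
                and self.cy + self.r_outer <= canvas[1])


@dataclass(frozen=True)
class Band:
    """Axis-aligned band: all points with lo <= coordinate-on-axis < hi."""
    axis: str  # "x" or "y"
    lo: float
    hi: float

    def __post_init__(self):
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")

    def contains(self, xy, canvas):
        c = xy[:, 0] if self.axis == "x" else xy[:, 1]
        return (c >= self.lo) & (c < self.hi)

    def area(self, canvas):
        other = canvas[1] if self.axis == "x" else canvas[0]
        return (self.hi - self.lo) * other

    def sample(self, n, canvas, rng):
        along = rng.uniform(self.lo, self.hi, size=n)
        other = rng.uniform(0.0, canvas[1] if self.axis == "x" else canvas[0], size=n)
        if self.axis == "x":
            return np.column_stack([along, other])
        return np.column_stack([other, along])

    def within_canvas(self, canvas):
        extent = canvas[0] if self.axis == "x" else canvas[1]
        return 0 <= self.lo and self.hi <= extent


Geometry = Background | Disk | Annulus | Band


@dataclass(frozen=True)
class RegionSpec:
    """One planted region: geometry, cell density, and type-mixture prior."""

    name: str
    geometry: Geometry
    density: float                      # cells per px^2
    concentration: tuple[float, ...]    # Dirichlet prior over the vocabulary

    def __post_init__(self):
        if not self.density > 0:
            raise ValueError(f"region {self.name!r}: density must be > 0")
        if any(c <= 0 for c in self.concentration):
            raise ValueError(f"region {self.name!r}: concentration must be positive")


@dataclass
class GroundTruth:
    """Truth channel for recovery tests: region per cell, realized mixtures."""

    region: np.ndarray                   # region name per cell
    mixtures: dict[str, np.ndarray]      # region name -> realized type mixture
    region_names: list[str]


def _validate_regions(regions: Sequence[RegionSpec],
                      canvas: tuple[float, float],
                      vocabulary: TypeVocabulary) -> None:
    if not regions:
        raise ValueError("need at least one region")
    if canvas[0] <= 0 or canvas[1] <= 0:
        raise ValueError(f"empty canvas {canvas}")
    if not isinstance(regions[0].geometry, Background):
        raise ValueError("first region must be a Background covering the canvas")
    names = [r.name for r in regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    for r in regions:
        if len(r.concentration) != len(vocabulary):
            raise ValueError(
                f"region {r.name!r}: concentration length {len(r.concentration)} "
                f"!= vocabulary size {len(vocabulary)}")
        if not r.geometry.within_canvas(canvas):
            raise ValueError(f"region {r.name!r} extends beyond the canvas")


def generate_tissue(regions: Sequence[RegionSpec],
                    canvas: tuple[float, float],
                    seed: int,
                    vocabulary: TypeVocabulary = DEFAULT_VOCABULARY,
                    sample_id: str = "synthetic",
                    ) -> tuple[CellTable, GroundTruth]:
    """Generate one synthetic sample with planted niches.

    Returns the cell table together with the ground-truth region label of
    every cell and each region's realized type mixture.
    """
    _validate_regions(regions, canvas, vocabulary)
    rng = np.random.default_rng(seed)

    placed: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for i, region in enumerate(regions):
        n = rng.poisson(region.density * region.geometry.area(canvas))
        pts = region.geometry.sample(n, canvas, rng)
        keep = np.ones(len(pts), dtype=bool)
        for later in regions[i + 1:]:
            keep &= ~later.geometry.contains(pts, canvas)
        placed.append(pts[keep])
        labels.append(np.full(keep.sum(), i, dtype=np.intp))
    xy = np.concatenate(placed) if placed else np.empty((0, 2))
    lab = np.concatenate(labels) if labels else np.empty(0, dtype=np.intp)

    mixtures = {}
    types = np.zeros(len(xy), dtype=np.intp)
    for i, region in enumerate(regions):
        p = rng.dirichlet(region.concentration)
        mixtures[region.name] = p
        mask = lab == i
        types[mask] = rng.choice(len(vocabulary), size=int(mask.sum()), p=p)

    frame = pd.DataFrame({
        "sample_id": sample_id,
        "cell_id": [f"c{i:06d}" for i in range(len(xy))],
        "x_px": xy[:, 0],
        "y_px": xy[:, 1],
        "cell_type": [vocabulary.names[t] for t in types],
    })
    truth = GroundTruth(region=np.array([regions[i].name for i in lab]),
                        mixtures=mixtures,
                        region_names=[r.name for r in regions])
    return CellTable(frame, vocabulary), truth


def generate_null_tissue(n_cells: int,
                         type_frequencies: Sequence[float],
                         canvas: tuple[float, float],
                         seed: int,
                         vocabulary: TypeVocabulary | None = None,
                         sample_id: str = "null",
                         ) -> CellTable:
    """Uniform random positions with i.i.d. type draws — no spatial structure.

    Calibration fixture: any downstream spatial enrichment is pure noise.
    """
    freqs = np.asarray(type_frequencies, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"type frequencies must sum to 1, got {freqs.sum()}")
    if vocabulary is None:
        vocabulary = TypeVocabulary.from_names(
            [f"T{i}" for i in range(len(freqs))])
    if len(freqs) != len(vocabulary):
        raise ValueError("frequency vector length must match vocabulary size")
    rng = np.random.default_rng(seed)
    xy = rng.uniform((0.0, 0.0), canvas, size=(n_cells, 2))
    types = rng.choice(len(vocabulary), size=n_cells, p=freqs)
    frame = pd.DataFrame({
        "sample_id": sample_id,
        "cell_id": [f"c{i:06d}" for i in range(n_cells)],
        "x_px": xy[:, 0] if n_cells else np.empty(0),
        "y_px": xy[:, 1] if n_cells else np.empty(0),
        "cell_type": [vocabulary.names[t] for t in types],
    })
    return CellTable(frame, vocabulary)


# ---------------------------------------------------------------------------
# The default planted-niche preset

BCC_CANVAS: tuple[float, float] = (3000.0, 3000.0)


def _mixture(vocabulary: TypeVocabulary, peak: float = 300.0,
             **weights: float) -> tuple[float, ...]:
    v = np.full(len(vocabulary), 0.01)
    for name, w in weights.items():
        v[vocabulary.index(name)] = w
    v = v / v.sum() * peak
    return tuple(v)


def bcc_preset(vocabulary: TypeVocabulary = DEFAULT_VOCABULARY,
               density: float = 2.2e-3) -> list[RegionSpec]:
    """Five planted regions mimicking the observed tumor architecture:
    background stroma, a tumor nodule, a stroma-deplete core inside the
    nodule, a myeloid-rich strip along the top edge, and an inflammatory
    tumor band abutting that strip.

    Geometry guarantees every ``bit_band`` cell lies nearer the myeloid
    strip than any ``bst_core`` cell.
    """
    mk = lambda **kw: _mixture(vocabulary, **kw)
    return [
        RegionSpec("stroma", Background(), density,
                   mk(Fibroblast=0.45, Vasculature=0.20, TCell=0.15,
                      Macrophage=0.08, Unknown=0.05)),
        RegionSpec("tumor", Disk(1600.0, 1700.0, 700.0), density,
                   mk(Tumor=0.80, Fibroblast=0.08, TCell=0.05)),
        RegionSpec("bst_core", Disk(1600.0, 1700.0, 350.0), density,
                   mk(BST=0.85, Tumor=0.08)),
        RegionSpec("myeloid_strip", Band("y", 0.0, 300.0), density,
                   mk(Macrophage=0.45, Neutrophil=0.30, DendriticCell=0.12,
                      TCell=0.05)),
        RegionSpec("bit_band", Band("y", 300.0, 600.0), density,
                   mk(BIT=0.70, Macrophage=0.15, Neutrophil=0.05)),
    ]


# ---------------------------------------------------------------------------
# Spot-level counts

@dataclass(frozen=True)
class SpotGenSpec:
    """Parameters for the negative-binomial spot-count generator."""

    n_rows: int = 10
    n_cols: int = 10
    pitch_um: float = 100.0
    diameter_um: float = 55.0
    n_genes: int = 200
    n_signature: int = 16
    baseline_mean: float = 5.0
    baseline_log_sd: float = 1.0        # per-gene log-normal baseline spread
    dispersion: float = 2.0
    uplift_log_fc: float = 2.0          # delta: signature mean scaled by exp(delta)
    uplift_region: str = "bit"

    def __post_init__(self):
        if self.pitch_um < self.diameter_um:
            raise ValueError("pitch must be >= spot diameter")
        if not (0 < self.n_signature <= self.n_genes):
            raise ValueError("signature subset must be a non-empty gene subset")
        if not math.isfinite(self.uplift_log_fc):
            raise ValueError("uplift must be finite")

    @property
    def signature_genes(self) -> list[str]:
        return [f"SIG{i + 1:03d}" for i in range(self.n_signature)]

    @property
    def gene_names(self) -> list[str]:
        rest = [f"G{i + 1:04d}" for i in range(self.n_genes - self.n_signature)]
        return self.signature_genes + rest


def generate_spots(spec: SpotGenSpec,
                   region_map: Callable[[np.ndarray], np.ndarray],
                   seed: int) -> tuple[SpotMatrix, np.ndarray]:
    """Generate a regular spot grid with negative-binomial counts.

    ``region_map`` maps an (n, 2) array of spot-center coordinates (same
    units as ``pitch_um``) to region labels; it must cover every center.
    Signature genes have their mean multiplied by exp(uplift_log_fc) in
    spots whose label equals ``spec.uplift_region``. Spot cluster labels are
    the region labels themselves.
    """
    rng = np.random.default_rng(seed)
    cols, rows = np.meshgrid(np.arange(spec.n_cols), np.arange(spec.n_rows))
    x = (cols.ravel() + 0.5) * spec.pitch_um
    y = (rows.ravel() + 0.5) * spec.pitch_um
    centers = np.column_stack([x, y])
    labels = np.asarray(region_map(centers))
    if labels.shape != (len(centers),) or pd.isna(labels).any():
        raise ValueError("region map must label every spot center")

    n_spots = len(centers)
    # heterogeneous per-gene baselines so expression bins are populated by
    # a mix of signature and non-signature genes
    base = spec.baseline_mean * np.exp(
        rng.normal(0.0, spec.baseline_log_sd, size=spec.n_genes))
    mean = np.tile(base, (n_spots, 1))
    uplifted = labels == spec.uplift_region
    mean[np.ix_(uplifted, np.arange(spec.n_signature))] *= math.exp(spec.uplift_log_fc)

    # Gamma-Poisson mixture: var = mu + mu^2 / dispersion
    lam = rng.gamma(shape=spec.dispersion, scale=mean / spec.dispersion)
    counts = rng.poisson(lam)

    matrix = SpotMatrix(counts, spec.gene_names,
                        [f"s{i:04d}" for i in range(n_spots)],
                        x, y, clusters=labels.astype(str))
    return matrix, labels


def half_plane_region_map(boundary_um: float, inside: str = "bit",
                          outside: str = "rest") -> Callable[[np.ndarray], np.ndarray]:
    """Simple two-region map: label spots with y < boundary as ``inside``."""
    def fn(centers: np.ndarray) -> np.ndarray:
        return np.where(centers[:, 1] < boundary_um, inside, outside)
    return fn
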