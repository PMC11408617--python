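"""Pipeline configuration and the cell-type vocabulary.

Configuration round-trips through a flat INI-style file (``key = value``
under sections) so a run manifest can reproduce the exact parameterization.
"""

from __future__ import annotations

import configparser
import dataclasses
import io
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class TypeVocabulary:
    """Ordered list of cell-type names with optional semantic subsets.

    Parameters
    ----------
    names
        Unique, non-empty cell-type labels in a fixed order. Composition
        vectors and enrichment matrices use this order for their columns.
    tumor_types, myeloid_types
        Optional subsets flagging which names denote tumor epithelium and
        myeloid lineages; every flagged name must be in ``names``.
    """

    names: tuple[str, ...]
    tumor_types: frozenset[str] = frozenset()
    myeloid_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("vocabulary must contain at least one type name")
        if any(not n for n in self.names):
            raise ValueError("type names must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise ValueError("type names must be unique")
        for flag, subset in (("tumor_types", self.tumor_types),
                             ("myeloid_types", self.myeloid_types)):
            unknown = set(subset) - set(self.names)
            if unknown:
                raise ValueError(f"{flag} references unknown names: {sorted(unknown)}")

    @classmethod
    def from_names(cls, names: Sequence[str], *,
                   tumor_types: Sequence[str] = (),
                   myeloid_types: Sequence[str] = ()) -> "TypeVocabulary":
        return cls(tuple(names), frozenset(tumor_types), frozenset(myeloid_types))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class PipelineConfig:
    """All tunable parameters of the spatial-niche pipeline.

    Defaults follow the published analysis: 100 nearest neighbors per cell,
    30 k-means micro-clusters per sample merged to ~10 communities, a
    2.65 px/um imaging calibration, and a top-10-percentile cutoff for
    signature-high spots.
    """

    k_neighbors: int = 100
    n_microclusters: int = 30
    n_communities: int = 10
    px_per_um: float = 2.65
    top_pct: float = 10.0
    n_bins: int = 24
    n_ctrl: int = 100
    n_restarts: int = 10
    include_self: bool = True
    seed_simulate: int = 0
    seed_cluster: int = 0
    seed_score: int = 0

    _INT_FIELDS = ("k_neighbors", "n_microclusters", "n_communities",
                   "n_bins", "n_ctrl", "n_restarts",
                   "seed_simulate", "seed_cluster", "seed_score")

    def __post_init__(self) -> None:
        for name in ("k_neighbors", "n_microclusters", "n_communities",
                     "n_bins", "n_ctrl", "n_restarts"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not self.px_per_um > 0:
            raise ValueError(f"px_per_um must be > 0, got {self.px_per_um!r}")
        if not 0 < self.top_pct < 100:
            raise ValueError(f"top_pct must lie in (0, 100), got {self.top_pct!r}")

    # -- INI round trip ----------------------------------------------------

    def to_ini(self) -> str:
        cp = configparser.ConfigParser()
        cp["pipeline"] = {}
        cp["seeds"] = {}
        for f in dataclasses.fields(self):
            section = "seeds" if f.name.startswith("seed_") else "pipeline"
            cp[section][f.name] = repr(getattr(self, f.name))
        buf = io.StringIO()
        cp.write(buf)
        return buf.getvalue()

    @classmethod
    def from_ini(cls, text: str) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        cp.read_string(text)
        kwargs = {}
        valid = {f.name: f for f in dataclasses.fields(cls)}
        for section in cp.sections():
            for key, raw in cp[section].items():
                if key not in valid:
                    raise ValueError(f"unknown config key {key!r}")
                if key in cls._INT_FIELDS:
                    kwargs[key] = int(raw)
                elif key == "include_self":
                    kwargs[key] = raw.strip() in ("True", "true", "1", "yes")
                else:
                    kwargs[key] = float(raw)
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_ini())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_ini(fh.read())


DEFAULT_VOCABULARY = TypeVocabulary.from_names(
    ["Tumor", "BST", "BIT", "Macrophage", "Neutrophil", "DendriticCell",
     "TCell", "Fibroblast", "Vasculature", "Unknown"],
    tumor_types=["Tumor", "BST", "BIT"],
    myeloid_types=["Macrophage", "Neutrophil", "DendriticCell"],
)
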