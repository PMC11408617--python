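"""Readers and writers for the delimited-text and MatrixMarket formats the
pipeline consumes and produces, plus the run manifest."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import PipelineConfig, TypeVocabulary


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


DEFAULT_CELL_COLUMNS = {
    "sample_id": "sample_id",
    "cell_id": "cell_id",
    "x": "x",
    "y": "y",
    "cell_type": "cell_type",
}

UNKNOWN_LABEL = "Unknown"


@dataclass
class CellTable:
    """Per-sample list of segmented cells with pixel centroids and type labels.

    ``frame`` holds columns ``sample_id, cell_id, x_px, y_px, cell_type``.
    Coordinates follow image convention (origin top-left, y increasing
    downward) and stay in pixels; unit calibration happens only inside the
    distance analysis.
    """

    frame: pd.DataFrame
    vocabulary: TypeVocabulary | None = None

    REQUIRED = ("sample_id", "cell_id", "x_px", "y_px", "cell_type")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ParseError(f"cell table missing columns: {missing}")
        f = self.frame
        xy = f[["x_px", "y_px"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
            raise ParseError(f"non-finite coordinates at row {bad}")
        if (xy < 0).any():
            bad = int(np.flatnonzero((xy < 0).any(axis=1))[0])
            raise ParseError(f"negative coordinates at row {bad}")
        bad_type = f["cell_type"].isna() | (f["cell_type"] == "")
        if bad_type.any():
            bad = int(np.flatnonzero(bad_type.to_numpy())[0])
            raise ParseError(f"missing cell type label at row {bad}")
        dup = f.duplicated(subset=["sample_id", "cell_id"])
        if dup.any():
            row = f[dup].iloc[0]
            raise ParseError(
                f"duplicate cell key (sample={row['sample_id']!r}, "
                f"cell={row['cell_id']!r})")
        if self.vocabulary is not None:
            unknown = set(f["cell_type"]) - set(self.vocabulary.names)
            if unknown:
                raise ParseError(f"labels outside vocabulary: {sorted(unknown)}")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def sample(self, sample_id: str) -> "CellTable":
        sub = self.frame[self.frame["sample_id"] == sample_id]
        return CellTable(sub.copy(), self.vocabulary)

    def coordinates(self) -> np.ndarray:
        return self.frame[["x_px", "y_px"]].to_numpy(dtype=float)

    def type_codes(self, vocabulary: TypeVocabulary) -> np.ndarray:
        """Integer codes of each cell's type in vocabulary order."""
        lut = {n: i for i, n in enumerate(vocabulary.names)}
        try:
            return np.array([lut[t] for t in self.frame["cell_type"]], dtype=np.intp)
        except KeyError as exc:
            raise ParseError(f"cell type {exc.args[0]!r} not in vocabulary") from None


def read_cell_table(path, vocabulary: TypeVocabulary | None = None, *,
                    columns: Mapping[str, str] | None = None,
                    strict: bool = False, sep: str = ",") -> CellTable:
    """Read a delimited cell table.

    ``columns`` remaps the default header names (sample_id, cell_id, x, y,
    cell_type). Unrecognized type labels raise in strict mode and map to
    ``"Unknown"`` otherwise.
    """
    cols = dict(DEFAULT_CELL_COLUMNS)
    if columns:
        cols.update(columns)
    try:
        # keep_default_na=False: sample names like "null" or "NA" are data
        raw = pd.read_csv(path, sep=sep, keep_default_na=False,
                          dtype={cols["sample_id"]: str,
                                 cols["cell_id"]: str,
                                 cols["cell_type"]: str})
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in cols.values() if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} "
                         f"(found {list(raw.columns)})")
    frame = pd.DataFrame({
        "sample_id": raw[cols["sample_id"]],
        "cell_id": raw[cols["cell_id"]],
        "cell_type": raw[cols["cell_type"]],
    })
    for out_name, in_name in (("x_px", cols["x"]), ("y_px", cols["y"])):
        try:
            frame[out_name] = pd.to_numeric(raw[in_name], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[in_name], errors="coerce")
            line = int(np.flatnonzero(bad.isna().to_numpy())[0]) + 2  # 1-based + header
            raise ParseError(f"{path}: non-numeric coordinate in column "
                             f"{in_name!r} at line {line}") from None
    frame = frame[["sample_id", "cell_id", "x_px", "y_px", "cell_type"]]
    if vocabulary is not None:
        known = set(vocabulary.names)
        mask = ~frame["cell_type"].isin(known)
        if mask.any():
            if strict:
                bad = sorted(set(frame.loc[mask, "cell_type"]))
                raise ParseError(f"{path}: unrecognized cell types {bad}")
            if UNKNOWN_LABEL not in known:
                raise ParseError(
                    f"{path}: unrecognized types present but vocabulary has "
                    f"no {UNKNOWN_LABEL!r} label to map them to")
            warnings.warn(f"{int(mask.sum())} cells with unrecognized types "
                          f"mapped to {UNKNOWN_LABEL!r}")
            frame.loc[mask, "cell_type"] = UNKNOWN_LABEL
    return CellTable(frame, vocabulary)


def write_cell_table(table: CellTable, path, *, sep: str = ",") -> None:
    table.frame.rename(columns={"x_px": "x", "y_px": "y"}).to_csv(
        path, sep=sep, index=False)


@dataclass
class SpotMatrix:
    """Spot x gene count matrix with spot coordinates and cluster labels."""

    counts: np.ndarray            # dense (n_spots, n_genes), non-negative ints
    genes: list[str]
    spot_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    clusters: np.ndarray | None = None   # per-spot label, optional

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ParseError("counts must be 2-D (spots x genes)")
        n, g = self.counts.shape
        if len(self.genes) != g:
            raise ParseError(f"matrix has {g} genes but {len(self.genes)} names")
        if len(self.spot_ids) != n:
            raise ParseError(f"matrix has {n} spots but {len(self.spot_ids)} ids")
        if len(set(self.genes)) != g:
            raise ParseError("gene names not unique")
        if len(set(self.spot_ids)) != n:
            raise ParseError("spot ids not unique")
        if (self.counts < 0).any():
            raise ParseError("negative counts")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != (n,) or self.y.shape != (n,):
            raise ParseError("coordinate arrays must have one entry per spot")
        if self.clusters is not None:
            self.clusters = np.asarray(self.clusters)
            if self.clusters.shape != (n,):
                raise ParseError("cluster labels must have one entry per spot")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def read_spot_matrix(matrix_path, genes_path, spots_path, *,
                     clusters_path=None) -> SpotMatrix:
    """Read a spot matrix from MatrixMarket (``.mtx``, genes x spots, the
    Visium export convention) or dense CSV (spots x genes), with sidecar
    files naming genes and spots.

    The spots sidecar is a CSV with columns ``spot_id, x, y``; the genes
    sidecar has one symbol per line; the optional clusters sidecar is a CSV
    with columns ``spot_id, cluster``.
    """
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines()
             if ln.strip()]
    spots = pd.read_csv(spots_path, keep_default_na=False, dtype={"spot_id": str})
    for col in ("spot_id", "x", "y"):
        if col not in spots.columns:
            raise ParseError(f"{spots_path}: missing column {col!r}")
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        m = scipy.io.mmread(matrix_path)
        counts = np.asarray(sp.coo_matrix(m).todense()).T  # genes x spots -> spots x genes
    else:
        counts = pd.read_csv(matrix_path, header=None).to_numpy()
    if counts.shape != (len(spots), len(genes)):
        raise ParseError(
            f"matrix shape {counts.shape} does not match sidecars "
            f"({len(spots)} spots x {len(genes)} genes)")
    counts = np.rint(counts).astype(np.int64)
    clusters = None
    if clusters_path is not None:
        cl = pd.read_csv(clusters_path, keep_default_na=False,
                         dtype={"spot_id": str})
        cl = cl.set_index("spot_id").reindex(spots["spot_id"])
        if cl["cluster"].isna().any():
            raise ParseError("cluster file does not cover every spot")
        clusters = cl["cluster"].to_numpy()
    return SpotMatrix(counts, genes, list(spots["spot_id"]),
                      spots["x"].to_numpy(), spots["y"].to_numpy(), clusters)


def write_spot_matrix(matrix: SpotMatrix, out_dir, *, stem: str = "spots") -> dict:
    """Write a SpotMatrix as MatrixMarket (genes x spots) plus sidecars.

    Returns the mapping of roles to file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / f"{stem}.mtx",
        "genes": out_dir / f"{stem}.genes.txt",
        "spots": out_dir / f"{stem}.spots.csv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(matrix.counts.T))
    paths["genes"].write_text("".join(g + "\n" for g in matrix.genes))
    pd.DataFrame({"spot_id": matrix.spot_ids, "x": matrix.x,
                  "y": matrix.y}).to_csv(paths["spots"], index=False)
    if matrix.clusters is not None:
        paths["clusters"] = out_dir / f"{stem}.clusters.csv"
        pd.DataFrame({"spot_id": matrix.spot_ids,
                      "cluster": matrix.clusters}).to_csv(
            paths["clusters"], index=False)
    return paths


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_table(frame: pd.DataFrame, path) -> None:
    """Write any pipeline result table as headered CSV with stable column order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def write_manifest(config: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    config.save(path)


def read_manifest(path) -> PipelineConfig:
    return PipelineConfig.load(path)
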