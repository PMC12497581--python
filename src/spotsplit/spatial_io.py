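"""Readers and writers for spatial-transcriptomics file formats.

Supports the 10X-style MatrixMarket triplet (``matrix.mtx`` + ``features.tsv``
+ ``barcodes.tsv``) with a ``tissue_positions.csv`` table, and the three
deconvolution output files (cell expression triplet, cell locations, cell
clusters).  All readers are gzip-transparent (a ``.gz`` suffix is enough).

Coordinate convention: the positions CSV uses the 10X column order
(barcode, in_tissue, array_row, array_col, pxl_row_in_fullres,
pxl_col_in_fullres); internally ``x = pxl_col`` and ``y = pxl_row``, and array
indices are 0-based.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

POSITIONS_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class SpatialIOError(ValueError):
    """Base class for spatial file-format errors."""


class MatrixFormatError(SpatialIOError):
    """The MatrixMarket file is malformed (bad header, 0-based indices, ...)."""


class HeaderMismatchError(SpatialIOError):
    """Matrix dimensions disagree with the features/barcodes files."""


class DuplicateBarcodeError(SpatialIOError):
    """A barcode or gene identifier occurs more than once."""


class NonIntegerEntryError(SpatialIOError):
    """The count matrix contains non-integer or negative entries."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class GeneSpotMatrix:
    """Sparse nonnegative integer UMI counts, genes x spots."""

    counts: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DuplicateBarcodeError("gene_ids contains duplicates")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise DuplicateBarcodeError("barcodes contains duplicates")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise NonIntegerEntryError("count matrix contains negative entries")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and np.any(data != np.round(data)):
                raise NonIntegerEntryError("count matrix contains non-integer entries")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.barcodes
        )


@dataclass
class SpotLayout:
    """Per-barcode tissue positions plus the physical spot radius (pixels)."""

    positions: pd.DataFrame  # index: barcode; columns: in_tissue, array_row, array_col, x, y
    spot_radius: float

    def __post_init__(self) -> None:
        if self.spot_radius <= 0:
            raise ValueError("spot_radius must be positive")
        if self.positions.index.has_duplicates:
            raise DuplicateBarcodeError("positions table has duplicate barcodes")
        required = {"in_tissue", "array_row", "array_col", "x", "y"}
        missing = required - set(self.positions.columns)
        if missing:
            raise ValueError(f"positions table missing columns: {sorted(missing)}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.positions.index)


@dataclass
class PutativeCellSet:
    """Deconvolved single cells: ids, module labels, source spots, positions, counts."""

    cell_ids: list[str]
    clusters: list[str]
    source_barcodes: list[str]
    x: np.ndarray
    y: np.ndarray
    counts: sp.csr_matrix  # genes x cells
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (len(self.clusters) == len(self.source_barcodes) == len(self.x) == len(self.y) == n):
            raise ValueError("cell attribute lengths disagree")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), n):
            raise ValueError("cell count matrix shape mismatch")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def _canonical_coo(matrix: sp.spmatrix) -> sp.coo_matrix:
    # column-major entry order makes write -> read -> write byte-stable
    m = sp.csc_matrix(matrix)
    m.sum_duplicates()
    m.sort_indices()
    return m.tocoo()


def _write_mtx(path: Path, matrix: sp.spmatrix) -> None:
    coo = _canonical_coo(matrix).astype(np.int64)
    scipy.io.mmwrite(str(path), coo, field="integer")


def _read_mtx(path: str | Path) -> sp.coo_matrix:
    path = Path(path)
    try:
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                mat = scipy.io.mmread(fh)
        else:
            mat = scipy.io.mmread(str(path))
    except Exception as exc:  # scipy raises bare ValueError without the file name
        raise MatrixFormatError(f"{path}: invalid MatrixMarket file ({exc})") from exc
    return sp.coo_matrix(mat)


def _read_single_column(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_spatial_dataset(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    positions_path: str | Path,
    spot_radius: float = 27.5,
) -> tuple[GeneSpotMatrix, SpotLayout]:
    """Read a Visium-style dataset restricted to in-tissue spots.

    Spots missing from the positions table (or flagged out of tissue) are
    dropped and counted in the log; gene order follows the features file
    exactly.
    """
    mat = _read_mtx(matrix_path)
    genes = _read_single_column(features_path)
    barcodes = _read_single_column(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise HeaderMismatchError(
            f"{matrix_path}: header declares {mat.shape[0]} x {mat.shape[1]} but "
            f"{features_path} has {len(genes)} genes and "
            f"{barcodes_path} has {len(barcodes)} barcodes"
        )
    if len(set(barcodes)) != len(barcodes):
        raise DuplicateBarcodeError(f"{barcodes_path}: duplicate barcodes")
    if len(set(genes)) != len(genes):
        raise DuplicateBarcodeError(f"{features_path}: duplicate gene identifiers")
    data = mat.data
    if data.size and (np.any(data != np.round(data)) or data.min() < 0):
        raise NonIntegerEntryError(
            f"{matrix_path}: matrix entries must be nonnegative integers"
        )

    pos = _read_positions(positions_path)
    in_tissue = pos[pos["in_tissue"] == 1]
    keep = [b for b in barcodes if b in set(in_tissue.index)]
    dropped = [b for b in barcodes if b not in set(in_tissue.index)]
    if dropped:
        logger.info(
            "read_spatial_dataset: dropped %d barcode(s) absent from the in-tissue "
            "positions (e.g. %s)",
            len(dropped),
            dropped[:3],
        )
    if not keep:
        raise SpatialIOError(f"{positions_path}: no in-tissue barcodes overlap the matrix")
    col_idx = [i for i, b in enumerate(barcodes) if b in set(keep)]
    counts = sp.csr_matrix(mat.tocsc()[:, col_idx]).astype(np.int64)
    matrix = GeneSpotMatrix(counts=counts, gene_ids=genes, barcodes=keep)
    layout = SpotLayout(positions=in_tissue.loc[keep], spot_radius=spot_radius)
    return matrix, layout


def _read_positions(path: str | Path) -> pd.DataFrame:
    with _open_text(path) as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=None if has_header else POSITIONS_COLUMNS,
        float_precision="round_trip",
    )
    if has_header:
        missing = set(POSITIONS_COLUMNS) - set(df.columns)
        if missing:
            raise SpatialIOError(f"{path}: positions file missing columns {sorted(missing)}")
    df = df[POSITIONS_COLUMNS].copy()
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise DuplicateBarcodeError(f"{path}: duplicate barcode {dup!r}")
    df = df.set_index("barcode")
    df["x"] = df["pxl_col_in_fullres"].astype(float)
    df["y"] = df["pxl_row_in_fullres"].astype(float)
    return df[["in_tissue", "array_row", "array_col", "x", "y"]]


def write_spatial_dataset(
    matrix: GeneSpotMatrix, layout: SpotLayout, out_dir: str | Path
) -> dict[str, Path]:
    """Write matrix.mtx / features.tsv / barcodes.tsv / tissue_positions.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "positions": out / "tissue_positions.csv",
    }
    _write_mtx(paths["matrix"], matrix.counts)
    with open(paths["features"], "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(b + "\n" for b in matrix.barcodes)
    pos = layout.positions.loc[matrix.barcodes]
    table = pd.DataFrame(
        {
            "barcode": pos.index,
            "in_tissue": pos["in_tissue"].astype(int).to_numpy(),
            "array_row": pos["array_row"].astype(int).to_numpy(),
            "array_col": pos["array_col"].astype(int).to_numpy(),
            "pxl_row_in_fullres": pos["y"].to_numpy(),
            "pxl_col_in_fullres": pos["x"].to_numpy(),
        }
    )
    table.to_csv(paths["positions"], index=False)
    return paths


def write_deconvolved(cells: PutativeCellSet, out_dir: str | Path) -> dict[str, Path]:
    """Write the three deconvolution outputs.

    (a) cell expression as a MatrixMarket triplet (matrix.mtx, features.tsv,
    cells.tsv), (b) cell locations CSV, (c) cell clusters CSV.  All three
    share the same cell_id ordering.
    """
    if cells.n_cells == 0:
        raise ValueError("write_deconvolved: empty cell set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "features": out / "features.tsv",
        "cells": out / "cells.tsv",
        "locations": out / "cell_locations.csv",
        "clusters": out / "cell_clusters.csv",
    }
    _write_mtx(paths["matrix"], cells.counts)
    with open(paths["features"], "w") as fh:
        for g in cells.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(paths["cells"], "w") as fh:
        fh.writelines(c + "\n" for c in cells.cell_ids)
    pd.DataFrame(
        {
            "cell_id": cells.cell_ids,
            "source_barcode": cells.source_barcodes,
            "x": cells.x,
            "y": cells.y,
        }
    ).to_csv(paths["locations"], index=False)
    pd.DataFrame({"cell_id": cells.cell_ids, "cluster": cells.clusters}).to_csv(
        paths["clusters"], index=False
    )
    return paths


def read_deconvolved(out_dir: str | Path) -> PutativeCellSet:
    """Read back the triplet written by :func:`write_deconvolved`."""
    out = Path(out_dir)
    mat = _read_mtx(out / "matrix.mtx")
    genes = _read_single_column(out / "features.tsv")
    cell_ids = _read_single_column(out / "cells.tsv")
    if mat.shape != (len(genes), len(cell_ids)):
        raise HeaderMismatchError(
            f"{out / 'matrix.mtx'}: dimensions disagree with features/cells files"
        )
    loc = (
        pd.read_csv(out / "cell_locations.csv", float_precision="round_trip")
        .set_index("cell_id")
        .loc[cell_ids]
    )
    clu = pd.read_csv(out / "cell_clusters.csv").set_index("cell_id").loc[cell_ids]
    return PutativeCellSet(
        cell_ids=cell_ids,
        clusters=[str(c) for c in clu["cluster"]],
        source_barcodes=[str(b) for b in loc["source_barcode"]],
        x=loc["x"].to_numpy(float),
        y=loc["y"].to_numpy(float),
        counts=sp.csr_matrix(mat).astype(np.int64),
        gene_ids=genes,
    )
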