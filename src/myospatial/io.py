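"""Readers and writers for the standard spatial gene-expression file layouts.

The on-disk convention follows Space Ranger / Cell Ranger: a matrix directory
holds ``matrix.mtx[.gz]`` (genes x barcodes), ``features.tsv[.gz]`` and
``barcodes.tsv[.gz]``; spot geometry lives in a ``tissue_positions`` CSV in
either dialect (with or without a header line).  In memory everything is
oriented spots x genes and carried in an :class:`anndata.AnnData`.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

logger = logging.getLogger(__name__)

#: geometry columns in Space Ranger order
POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"{directory}: missing {stem}[.gz]")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_mtx_trio(directory) -> tuple[sp.csr_matrix, pd.Index, pd.Index]:
    """Load a matrix directory and return ``(spots x genes, genes, barcodes)``.

    The on-disk matrix is genes x barcodes (ecosystem convention); it is
    transposed on load so that rows are spots.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")

    feat_rows = [line.split("\t") for line in _read_tsv_column(feat_path)]
    if not feat_rows:
        raise FormatError(f"{feat_path}: no features listed")
    # 1-3 column dialects; the gene identifier is column 2 when present
    genes = pd.Index([row[1] if len(row) >= 2 else row[0] for row in feat_rows])
    barcodes = pd.Index(_read_tsv_column(bc_path))
    if len(barcodes) == 0:
        raise FormatError(f"{bc_path}: no barcodes listed")

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[0]} rows but {feat_path.name} lists {len(genes)} features"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[1]} columns but {bc_path.name} lists {len(barcodes)} barcodes"
        )
    return sp.csr_matrix(mat.T), genes, barcodes


def write_mtx_trio(directory, matrix, genes, barcodes) -> None:
    """Write a spots x genes matrix as a genes x barcodes MTX trio."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(sp.csr_matrix(matrix).T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), mat)
    with open(directory / "features.tsv", "w") as fh:
        for g in genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in barcodes:
            fh.write(f"{b}\n")


def read_tissue_positions(path) -> pd.DataFrame:
    """Parse a tissue-positions CSV (header and headerless dialects).

    Returns a DataFrame with :data:`POSITION_COLUMNS`; ``in_tissue`` is
    boolean and array indices are integers.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
    has_header = first.lower().startswith("barcode")
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 columns, found {df.shape[1]}")
    df.columns = POSITION_COLUMNS
    for col in ("array_row", "array_col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, vals.round()):
            raise FormatError(f"{path}: non-integer values in {col}")
        df[col] = vals.astype(int)
    df["in_tissue"] = df["in_tissue"].astype(int).astype(bool)
    if df["barcode"].duplicated().any():
        dup = df["barcode"][df["barcode"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate barcode {dup!r}")
    return df.reset_index(drop=True)


def write_tissue_positions(path, positions: pd.DataFrame, header: bool = True) -> None:
    positions[POSITION_COLUMNS].to_csv(path, index=False, header=header)


def compute_qc(adata: ad.AnnData) -> ad.AnnData:
    """Attach per-spot nCount (total UMIs) and nFeature (detected genes)."""
    X = sp.csr_matrix(adata.X)
    adata.obs["nCount"] = np.asarray(X.sum(axis=1)).ravel()
    adata.obs["nFeature"] = np.asarray((X > 0).sum(axis=1)).ravel()
    return adata


def assemble_dataset(matrix_dir, positions, layer_dirs=None) -> ad.AnnData:
    """Assemble an in-tissue spots x genes AnnData from on-disk pieces.

    Parameters
    ----------
    matrix_dir : path
        MTX trio of the total (spliced+unspliced) counts.
    positions : path or DataFrame
        Tissue-positions table covering the matrix barcodes.
    layer_dirs : dict[str, path], optional
        Additional MTX trios (e.g. ``{"spliced": ..., "unspliced": ...}``)
        sharing the gene list; barcodes may be a subset (missing spots get
        zero rows, with a logged warning).
    """
    X, genes, barcodes = read_mtx_trio(matrix_dir)
    if not isinstance(positions, pd.DataFrame):
        positions = read_tissue_positions(positions)
    positions = positions.set_index("barcode")

    shared = barcodes.intersection(positions.index)
    if len(shared) == 0:
        raise FormatError("no overlap between matrix barcodes and tissue positions")
    n_dropped_matrix = len(barcodes) - len(shared)
    n_dropped_pos = len(positions) - len(shared)
    if n_dropped_matrix:
        logger.warning("%d matrix barcodes absent from positions; dropped", n_dropped_matrix)
    if n_dropped_pos:
        logger.warning("%d position barcodes absent from matrix; dropped", n_dropped_pos)

    keep = barcodes.isin(shared)
    barcodes = barcodes[keep]
    X = X[np.flatnonzero(keep)]
    geom = positions.loc[barcodes]

    obs = geom.copy()
    obs.insert(0, "barcode", obs.index.to_numpy())
    obs.index = pd.Index(obs.index.to_numpy().astype(str), name=None)
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))

    for name, ldir in (layer_dirs or {}).items():
        L, lgenes, lbarcodes = read_mtx_trio(ldir)
        if not lgenes.equals(genes):
            raise FormatError(f"layer {name!r}: gene list differs from the main matrix")
        layer = sp.lil_matrix((adata.n_obs, adata.n_vars), dtype=L.dtype)
        pos = pd.Series(np.arange(len(lbarcodes)), index=lbarcodes)
        present = adata.obs_names.isin(pos.index)
        if (~present).sum():
            logger.warning(
                "layer %r: %d spots missing; treated as zero", name, int((~present).sum())
            )
        idx = pos.loc[adata.obs_names[present]].to_numpy()
        layer[np.flatnonzero(present)] = L[idx]
        adata.layers[name] = sp.csr_matrix(layer)

    adata = adata[adata.obs["in_tissue"].to_numpy()].copy()
    compute_qc(adata)
    return adata
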