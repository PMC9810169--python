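"""Readers/writers for count matrices (dense CSV/TSV and Matrix Market)."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from scsem.data import CountMatrix
from scsem.errors import InputFormatError

_GENE_FILE_CANDIDATES = ("genes.tsv", "features.tsv")


def _find_companion(mtx_path: str, names: tuple[str, ...]) -> str:
    d = os.path.dirname(os.path.abspath(mtx_path))
    for name in names:
        p = os.path.join(d, name)
        if os.path.exists(p):
            return p
    raise InputFormatError(
        f"no companion file among {names} next to {mtx_path}"
    )


def read_counts(
    path: str,
    format: str = "csv",
    orientation: str | None = None,
) -> CountMatrix:
    """Read a raw count matrix from disk.

    Parameters
    ----------
    path
        CSV/TSV file (header row = gene names, first column = cell ids) or
        a Matrix Market ``.mtx`` file accompanied by ``barcodes.tsv`` (cell
        ids) and ``genes.tsv``/``features.tsv`` (gene ids) in its directory.
    format
        ``"csv"`` or ``"mtx"``.
    orientation
        ``"cells-rows"`` or ``"genes-rows"`` as stored on disk.  Defaults to
        cells-rows for CSV and genes-rows for MTX (the CellRanger layout).
    """
    if not os.path.exists(path):
        raise InputFormatError(f"input file not found: {path}")
    if format == "csv":
        orientation = orientation or "cells-rows"
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001 - rewrap with file name
            raise InputFormatError(f"failed to parse {path}: {exc}") from exc
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise InputFormatError(f"non-numeric entries in {path}")
        if orientation == "genes-rows":
            values = values.T
            cell_ids, gene_ids = list(df.columns), list(df.index)
        else:
            cell_ids, gene_ids = list(df.index), list(df.columns)
        try:
            return CountMatrix(values, cell_ids, gene_ids)
        except InputFormatError as exc:
            raise InputFormatError(f"{path}: {exc}") from exc
    if format == "mtx":
        orientation = orientation or "genes-rows"
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # noqa: BLE001
            raise InputFormatError(f"failed to parse {path}: {exc}") from exc
        mat = np.asarray(mat.todense()) if scipy.sparse.issparse(mat) else np.asarray(mat)
        barcodes_path = _find_companion(path, ("barcodes.tsv",))
        genes_path = _find_companion(path, _GENE_FILE_CANDIDATES)
        cell_ids = pd.read_csv(barcodes_path, sep="\t", header=None)[0].tolist()
        gdf = pd.read_csv(genes_path, sep="\t", header=None)
        gene_ids = gdf[0].tolist()
        if orientation == "genes-rows":
            mat = mat.T
        if mat.shape[0] != len(cell_ids):
            raise InputFormatError(
                f"{barcodes_path}: {len(cell_ids)} barcodes for "
                f"{mat.shape[0]} matrix rows"
            )
        if mat.shape[1] != len(gene_ids):
            raise InputFormatError(
                f"{genes_path}: {len(gene_ids)} genes for "
                f"{mat.shape[1]} matrix columns"
            )
        try:
            return CountMatrix(mat, cell_ids, gene_ids)
        except InputFormatError as exc:
            raise InputFormatError(f"{path}: {exc}") from exc
    raise InputFormatError(f"unknown format {format!r} (expected 'csv' or 'mtx')")


def write_counts(
    cm: CountMatrix,
    path: str,
    format: str = "csv",
    orientation: str | None = None,
) -> None:
    """Write a CountMatrix in a layout :func:`read_counts` round-trips."""
    if format == "csv":
        orientation = orientation or "cells-rows"
        df = pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids)
        if orientation == "genes-rows":
            df = df.T
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
        df.to_csv(path, sep=sep)
        return
    if format == "mtx":
        orientation = orientation or "genes-rows"
        d = os.path.dirname(os.path.abspath(path))
        os.makedirs(d, exist_ok=True)
        mat = scipy.sparse.coo_matrix(
            cm.counts.T if orientation == "genes-rows" else cm.counts
        )
        scipy.io.mmwrite(path if path.endswith(".mtx") else path + ".mtx", mat)
        with open(os.path.join(d, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(cm.cell_ids) + "\n")
        with open(os.path.join(d, "genes.tsv"), "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        return
    raise InputFormatError(f"unknown format {format!r} (expected 'csv' or 'mtx')")


def read_labels(path: str) -> pd.DataFrame:
    """Read a labels table (cell_id, group[, batch]) written by the simulator."""
    if not os.path.exists(path):
        raise InputFormatError(f"labels file not found: {path}")
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)
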