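"""Core in-memory containers: raw counts and their preprocessed views."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scsem.errors import InputFormatError


@dataclass
class CountMatrix:
    """A cells x genes matrix of raw, non-negative integer read counts.

    Internal orientation is always cells-as-rows; readers transpose on
    ingest when the on-disk layout is genes x cells.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise InputFormatError("counts must be a 2-D matrix")
        n, g = self.counts.shape
        if n < 2 or g < 1:
            raise InputFormatError(f"need at least 2 cells and 1 gene, got {n} x {g}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)):
                raise InputFormatError("counts contain non-finite entries")
            rounded = np.rint(self.counts)
            if not np.array_equal(rounded, self.counts):
                raise InputFormatError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            raise InputFormatError("counts must be non-negative")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g_) for g_ in self.gene_ids]
        if len(self.cell_ids) != n:
            raise InputFormatError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise InputFormatError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        if len(set(self.cell_ids)) != n:
            raise InputFormatError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != g:
            raise InputFormatError("duplicate gene identifiers")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[:, idx],
            cell_ids=list(self.cell_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
        )


@dataclass
class PreprocessedData:
    """Paired raw-count / encoder-input views after gene selection.

    ``raw`` is the ZINB likelihood target; ``encoder_input`` is the
    size-factor normalized, log2(x+1), per-gene z-scored matrix the encoder
    consumes.  Both share cell ordering and gene set.  ``size_factors``
    holds the per-cell scaling constants s_i; ``hvg_mask`` records which of
    the original (filtered) genes were retained.
    """

    raw: CountMatrix
    encoder_input: np.ndarray
    size_factors: np.ndarray
    hvg_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.encoder_input = np.asarray(self.encoder_input, dtype=np.float64)
        self.size_factors = np.asarray(self.size_factors, dtype=np.float64)
        if self.encoder_input.shape != self.raw.counts.shape:
            raise InputFormatError("raw and encoder_input shapes differ")
        if self.size_factors.shape != (self.raw.n_cells,):
            raise InputFormatError("size_factors length mismatch")
        if not np.all(np.isfinite(self.size_factors)) or (self.size_factors <= 0).any():
            raise InputFormatError("size factors must be positive and finite")
        if not np.all(np.isfinite(self.encoder_input)):
            raise InputFormatError("encoder input contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.raw.n_cells

    @property
    def n_genes(self) -> int:
        return self.raw.n_genes
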