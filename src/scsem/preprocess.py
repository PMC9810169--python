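"""Count preprocessing: gene filtering, size factors, normalization, HVG.

The pipeline follows the standard single-cell order of operations:
size-factor (median-of-ratios) normalization, log2(x + 1), then per-gene
z-scoring to zero mean / unit variance over cells.  Highly variable genes
are ranked by a mean-binned normalized dispersion of the log-normalized
values, and the top ``n_top`` (default 2000) genes are kept as a first
noise-reduction step.
"""

from __future__ import annotations

import logging

import numpy as np

from scsem.data import CountMatrix, PreprocessedData
from scsem.errors import DegenerateInputError

log = logging.getLogger(__name__)

N_DISPERSION_BINS = 20


def filter_unexpressed_genes(cm: CountMatrix) -> CountMatrix:
    """Drop genes with zero counts in every cell; cells are untouched."""
    expressed = (cm.counts > 0).any(axis=0)
    if not expressed.any():
        raise DegenerateInputError("no gene is expressed in any cell")
    if expressed.all():
        return cm
    return cm.subset_genes(expressed)


def compute_size_factors(cm: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factor s_i for each cell.

    For each gene with a strictly positive geometric mean over cells
    (i.e. no zero count anywhere), compute counts[i, j] / geomean_j; s_i is
    the median of those ratios over eligible genes.  Cells whose median is
    zero — and datasets with no eligible gene at all — fall back to
    library size divided by the mean library size, which keeps every s_i
    strictly positive on sparse data.
    """
    counts = cm.counts.astype(np.float64)
    all_positive = (cm.counts > 0).all(axis=0)
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        raise DegenerateInputError("a cell has zero total counts")
    fallback = lib / lib.mean()
    if not all_positive.any():
        log.warning("no gene expressed in all cells; size factors from library size")
        return fallback
    logc = np.log(counts[:, all_positive])
    geomean = np.exp(logc.mean(axis=0))
    ratios = counts[:, all_positive] / geomean
    s = np.median(ratios, axis=1)
    bad = ~(s > 0)
    if bad.any():
        s[bad] = fallback[bad]
    return s


def normalize_transform(cm: CountMatrix, size_factors: np.ndarray) -> np.ndarray:
    """Size-factor normalize, log2(x + 1), then z-score each gene over cells.

    Genes that are constant after the log transform are set to exactly 0 so
    the encoder input stays finite.
    """
    size_factors = np.asarray(size_factors, dtype=np.float64)
    if (size_factors <= 0).any():
        raise DegenerateInputError("size factors must be strictly positive")
    x = cm.counts / size_factors[:, None]
    x = np.log2(x + 1.0)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return out


def lognorm_matrix(cm: CountMatrix, size_factors: np.ndarray) -> np.ndarray:
    """log2(counts / s_i + 1) without the final z-scoring (HVG statistic input)."""
    return np.log2(cm.counts / np.asarray(size_factors, dtype=np.float64)[:, None] + 1.0)


def hvg_scores(lognorm: np.ndarray) -> np.ndarray:
    """Mean-binned normalized dispersion of each gene.

    dispersion_j = var_j / mean_j of the log-normalized values; genes are
    cut into ``N_DISPERSION_BINS`` equal-width bins of mean expression and
    the dispersion is z-scored within each bin (bins with a single gene or
    zero spread get score 0).  Ties are broken by gene index downstream.
    """
    mean = lognorm.mean(axis=0)
    var = lognorm.var(axis=0)
    disp = np.zeros_like(mean)
    pos = mean > 0
    disp[pos] = var[pos] / mean[pos]
    edges = np.linspace(mean.min(), mean.max(), N_DISPERSION_BINS + 1)
    bin_idx = np.clip(np.digitize(mean, edges[1:-1]), 0, N_DISPERSION_BINS - 1)
    score = np.zeros_like(disp)
    for b in range(N_DISPERSION_BINS):
        sel = bin_idx == b
        if not sel.any():
            continue
        d = disp[sel]
        sd = d.std()
        score[sel] = (d - d.mean()) / sd if sd > 0 else 0.0
    return score


def select_hvg(
    encoder_matrix: np.ndarray,
    raw: CountMatrix,
    size_factors: np.ndarray,
    n_top: int = 2000,
) -> PreprocessedData:
    """Keep the top ``n_top`` highly variable genes in both views."""
    g = raw.n_genes
    if n_top >= g:
        if n_top > g:
            log.warning("n_top=%d >= %d genes; keeping all genes", n_top, g)
        mask = np.ones(g, dtype=bool)
    else:
        score = hvg_scores(lognorm_matrix(raw, size_factors))
        # stable argsort on negated score => ties broken by gene index
        order = np.argsort(-score, kind="stable")
        mask = np.zeros(g, dtype=bool)
        mask[order[:n_top]] = True
    return PreprocessedData(
        raw=raw.subset_genes(mask),
        encoder_input=np.asarray(encoder_matrix)[:, mask],
        size_factors=np.asarray(size_factors, dtype=np.float64),
        hvg_mask=mask,
    )


def preprocess(cm: CountMatrix, n_top: int = 2000) -> PreprocessedData:
    """Full preprocessing chain: filter -> size factors -> normalize -> HVG."""
    cm = filter_unexpressed_genes(cm)
    s = compute_size_factors(cm)
    enc = normalize_transform(cm, s)
    return select_hvg(enc, cm, s, n_top=n_top)
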