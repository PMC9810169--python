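"""Hierarchical scRNA-seq count simulator with groups, batches and dropout.

The generative model follows the standard single-cell simulation recipe
(gamma-Poisson with multiplicative group / batch / library factors and
logistic zero inflation):

1. per-gene base mean  m_j ~ Gamma(mean_shape, mean_scale)
2. per-group DE: a de_prob fraction of genes gets a multiplicative
   log-normal(de_logfc_loc, de_logfc_sd) factor, inverted with probability
   1/2 (down-regulation)
3. per-batch log-normal(0, batch_logfc_sd) factor on every gene
4. per-cell library size L_i ~ log-normal(lib_loc, lib_scale); each cell's
   gene means are renormalized to sum to L_i
5. counts X_ij ~ Poisson(lambda_ij)
6. dropout: each entry is zeroed with probability
   sigmoid(-dropout_shape * (log lambda_ij - x0)) — higher-expressed
   entries drop out less, matching the zero-inflation structure the ZINB
   autoencoder assumes.  The midpoint x0 is calibrated by bisection so the
   expected fraction of *added* zeros (entries with a positive count that
   the mask removes) matches ``dropout_rate`` to within 0.01.

Group and batch memberships are exact-quota (largest remainder) so that a
balanced 5-group, 1000-cell design yields exactly 200 cells per group; the
order of cells is then shuffled.  All draws come from one seeded
generator, in the fixed order above, so fixtures are stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from scsem.data import CountMatrix
from scsem.errors import CalibrationError, ConfigError


@dataclass
class SimConfig:
    n_cells: int = 500
    n_genes: int = 2000
    n_groups: int = 2
    group_props: list[float] | None = None  # None => balanced
    n_batches: int = 2
    de_prob: float = 0.3
    de_logfc_loc: float = 1.0
    de_logfc_sd: float = 0.4
    batch_logfc_sd: float = 0.15
    lib_loc: float = float(np.log(20000.0))
    lib_scale: float = 0.25
    dropout_rate: float = 0.05
    dropout_shape: float = 1.0
    mean_shape: float = 0.6
    mean_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise ConfigError("need at least 2 cells and 1 gene")
        if self.n_groups < 1 or self.n_batches < 1:
            raise ConfigError("n_groups and n_batches must be >= 1")
        if self.group_props is None:
            self.group_props = [1.0 / self.n_groups] * self.n_groups
        self.group_props = [float(p) for p in self.group_props]
        if len(self.group_props) != self.n_groups:
            raise ConfigError("group_props length must equal n_groups")
        if abs(sum(self.group_props) - 1.0) > 1e-8 or min(self.group_props) < 0:
            raise ConfigError("group_props must be non-negative and sum to 1")
        for name in ("de_prob", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass
class SimResult:
    counts: CountMatrix
    group_labels: np.ndarray
    batch_labels: np.ndarray
    true_means: np.ndarray
    dropout_mask: np.ndarray
    config: SimConfig = field(repr=False, default=None)


def _quota_assign(n: int, props: list[float]) -> np.ndarray:
    """Largest-remainder allocation of n items to len(props) classes."""
    raw = np.asarray(props) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return np.repeat(np.arange(len(props)), base)


def _calibrate_dropout(p_of_x0, counts_nonzero: np.ndarray, target: float,
                       lo: float, hi: float) -> float:
    """Bisect the logistic midpoint so mean(p * nonzero) == target."""
    def f(x0):
        return float(np.mean(p_of_x0(x0) * counts_nonzero))

    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo <= target <= f_hi):
        raise CalibrationError(
            f"dropout_rate={target:.3g} outside achievable range "
            f"[{f_lo:.3g}, {f_hi:.3g}]"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_counts(cfg: SimConfig) -> SimResult:
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes

    base = rng.gamma(shape=cfg.mean_shape, scale=cfg.mean_scale, size=g)
    base = np.maximum(base, 1e-8)

    group_fac = np.ones((cfg.n_groups, g))
    for k in range(cfg.n_groups):
        de = rng.random(g) < cfg.de_prob
        fac = rng.lognormal(cfg.de_logfc_loc, cfg.de_logfc_sd, size=g)
        down = rng.random(g) < 0.5
        fac = np.where(down, 1.0 / fac, fac)
        group_fac[k, de] = fac[de]

    batch_fac = np.ones((cfg.n_batches, g))
    for b in range(cfg.n_batches):
        batch_fac[b] = rng.lognormal(0.0, cfg.batch_logfc_sd, size=g)

    groups = _quota_assign(n, cfg.group_props)
    groups = groups[rng.permutation(n)]
    batches = rng.permutation(np.arange(n) % cfg.n_batches)

    lib = rng.lognormal(cfg.lib_loc, cfg.lib_scale, size=n)

    mean = base[None, :] * group_fac[groups] * batch_fac[batches]
    mean = mean / mean.sum(axis=1, keepdims=True) * lib[:, None]

    counts = rng.poisson(mean).astype(np.int64)

    if cfg.dropout_rate > 0:
        logm = np.log(mean + 1e-12)

        def p_of_x0(x0):
            return expit(-cfg.dropout_shape * (logm - x0))

        x0 = _calibrate_dropout(
            p_of_x0, (counts > 0).astype(np.float64), cfg.dropout_rate,
            lo=float(logm.min()) - 40.0, hi=float(logm.max()) + 40.0,
        )
        mask = rng.random(mean.shape) < p_of_x0(x0)
        counts = np.where(mask, 0, counts)
    else:
        mask = np.zeros(mean.shape, dtype=bool)

    cm = CountMatrix(
        counts,
        cell_ids=[f"cell_{i}" for i in range(n)],
        gene_ids=[f"gene_{j}" for j in range(g)],
    )
    return SimResult(cm, groups, batches, mean, mask, cfg)


def make_easy_fixture(seed: int = 0) -> SimResult:
    """Low-dropout balanced design: 1000 cells, 2000 genes, 5 groups, 2 batches,
    dropout 0.05, strong group DE."""
    return simulate_counts(SimConfig(
        n_cells=1000, n_genes=2000, n_groups=5, n_batches=2,
        de_prob=0.3, de_logfc_loc=1.2, de_logfc_sd=0.4,
        dropout_rate=0.05, seed=seed,
    ))


def make_hard_fixture(seed: int = 0) -> SimResult:
    """High-dropout unbalanced design: 500 cells, 5 groups with proportions
    [0.4, 0.3, 0.15, 0.1, 0.05], 2 batches, dropout 0.25."""
    return simulate_counts(SimConfig(
        n_cells=500, n_genes=2000, n_groups=5,
        group_props=[0.4, 0.3, 0.15, 0.1, 0.05], n_batches=2,
        de_prob=0.3, de_logfc_loc=1.2, de_logfc_sd=0.4,
        dropout_rate=0.25, seed=seed,
    ))


def write_sim(result: SimResult, outdir: str, format: str = "csv") -> dict[str, str]:
    """Write counts + labels in the dialects the readers accept; returns paths."""
    from scsem.io import write_counts

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    if format == "csv":
        counts_path = os.path.join(outdir, "counts.csv")
    elif format == "mtx":
        counts_path = os.path.join(outdir, "matrix.mtx")
    else:
        raise ConfigError(f"unknown format {format!r}")
    write_counts(result.counts, counts_path, format=format)
    paths["counts"] = counts_path
    labels_path = os.path.join(outdir, "labels.csv")
    pd.DataFrame(
        {"group": result.group_labels, "batch": result.batch_labels},
        index=result.counts.cell_ids,
    ).rename_axis("cell_id").to_csv(labels_path)
    paths["labels"] = labels_path
    return paths
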