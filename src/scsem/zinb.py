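"""Numerically stable NB / ZINB log-pmfs and the ZINB negative log-likelihood.

The zero-inflated negative binomial models an scRNA-seq count X_ij as a
mixture of a point mass at zero (dropout, probability pi) and a negative
binomial with mean mu and dispersion theta:

    NB(x; mu, theta)   = Gamma(x + theta) / (x! Gamma(theta))
                         * (theta / (theta + mu))^theta
                         * (mu / (theta + mu))^x
    ZINB(x; pi, mu, theta) = pi * delta_0(x) + (1 - pi) * NB(x; mu, theta)

All evaluations run in log space through log-gamma; the x = 0 branch uses a
log-sum-exp of {log pi, log(1 - pi) + theta (log theta - log(theta + mu))}
so it stays finite as pi -> 0 with large mu.  Parameters are clamped before
evaluation because the exponential/sigmoid network heads can overflow:
theta in [1e-4, 1e4], mu in [1e-5, 1e6], pi in [1e-6, 1 - 1e-6].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

THETA_MIN, THETA_MAX = 1e-4, 1e4
MU_MIN, MU_MAX = 1e-5, 1e6
PI_EPS = 1e-6


def clamp_params(
    mu: np.ndarray, theta: np.ndarray, pi: np.ndarray | None = None
) -> tuple[np.ndarray, ...]:
    """Clamp ZINB parameters into their numerically safe ranges."""
    mu = np.clip(mu, MU_MIN, MU_MAX)
    theta = np.clip(theta, THETA_MIN, THETA_MAX)
    if pi is None:
        return mu, theta
    return mu, theta, np.clip(pi, PI_EPS, 1.0 - PI_EPS)


@dataclass
class ZINBParams:
    """Per-entry ZINB parameter matrices (same shape as the count target)."""

    mean: np.ndarray
    dispersion: np.ndarray
    dropout: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.dispersion = np.asarray(self.dispersion, dtype=np.float64)
        self.dropout = np.asarray(self.dropout, dtype=np.float64)
        if not (self.mean.shape == self.dispersion.shape == self.dropout.shape):
            raise ValueError("mean, dispersion, dropout must share a shape")
        self.mean, self.dispersion, self.dropout = clamp_params(
            self.mean, self.dispersion, self.dropout
        )


def _validate(mu, theta) -> tuple[np.ndarray, np.ndarray]:
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if (mu <= 0).any() or (theta <= 0).any():
        raise ValueError("mu and theta must be strictly positive")
    return mu, theta


def nb_log_pmf(x, mu, theta) -> np.ndarray:
    """Elementwise log NB(x; mu, theta), finite for all valid inputs."""
    mu, theta = _validate(mu, theta)
    x = np.asarray(x, dtype=np.float64)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    log_theta_mu = np.log(theta + mu)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mu) - log_theta_mu)
    )


def zinb_log_pmf(x, mu, theta, pi) -> np.ndarray:
    """Elementwise log ZINB(x; pi, mu, theta)."""
    pi = np.asarray(pi, dtype=np.float64)
    if (pi < 0).any() or (pi > 1).any():
        raise ValueError("pi must lie in [0, 1]")
    mu, theta = _validate(mu, theta)
    x = np.asarray(x, dtype=np.float64)
    x, mu, theta, pi = np.broadcast_arrays(x, mu, theta, pi)
    pi_c = np.clip(pi, PI_EPS, 1.0 - PI_EPS)
    nb = nb_log_pmf(x, mu, theta)
    # x == 0: logaddexp(log pi, log(1-pi) + NB(0)); keep exact limits at pi in {0,1}
    nb0 = theta * (np.log(theta) - np.log(theta + mu))
    zero_case = np.where(
        pi >= 1.0,
        0.0,
        np.where(
            pi <= 0.0,
            nb0,
            np.logaddexp(np.log(pi_c), np.log1p(-pi_c) + nb0),
        ),
    )
    pos_case = np.where(pi >= 1.0, -np.inf, np.log1p(-np.clip(pi, 0.0, 1.0 - PI_EPS)) + nb)
    return np.where(x == 0, zero_case, pos_case)


def zinb_nll(x, params: ZINBParams, reduction: str = "sum") -> float:
    """Negative log ZINB likelihood of the raw counts.

    ``reduction='sum'`` (the training term) returns
    sum_ij -log ZINB(X_ij); ``'mean'`` divides by the entry count.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape != params.mean.shape:
        raise ValueError(f"shape mismatch: counts {x.shape} vs params {params.mean.shape}")
    ll = zinb_log_pmf(x, params.mean, params.dispersion, params.dropout)
    nll = -ll.sum()
    if reduction == "mean":
        return float(nll / x.size)
    if reduction != "sum":
        raise ValueError("reduction must be 'sum' or 'mean'")
    return float(nll)


__all__ = [
    "ZINBParams",
    "nb_log_pmf",
    "zinb_log_pmf",
    "zinb_nll",
    "clamp_params",
    "THETA_MIN",
    "THETA_MAX",
    "MU_MIN",
    "MU_MAX",
    "PI_EPS",
    "logsumexp",
]
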