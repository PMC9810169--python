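"""External clustering agreement metrics: ACC, NMI, ARI.

Labels on both sides are opaque categories; every metric here is invariant
to bijective relabeling.  ACC is optimal-assignment accuracy: the best
one-to-one matching of predicted to true clusters (rectangular Hungarian
assignment on the contingency table; unmatched clusters contribute zero).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix


def _check(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError(f"label shape mismatch: {truth.shape} vs {pred.shape}")
    return truth, pred


def acc(truth, pred) -> float:
    """Optimal-assignment clustering accuracy in [0, 1]."""
    truth, pred = _check(truth, pred)
    w = contingency_matrix(truth, pred)
    row, col = linear_sum_assignment(-w)
    return float(w[row, col].sum() / truth.size)


def nmi(truth, pred, average_method: str = "arithmetic") -> float:
    """Normalized mutual information (arithmetic-mean normalizer by default)."""
    truth, pred = _check(truth, pred)
    return float(
        normalized_mutual_info_score(truth, pred, average_method=average_method)
    )


def ari(truth, pred) -> float:
    """Adjusted Rand index via the pair-counting contingency formula."""
    truth, pred = _check(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def metrics_report(truth, pred) -> dict[str, float]:
    return {"ACC": acc(truth, pred), "NMI": nmi(truth, pred), "ARI": ari(truth, pred)}


def write_metrics_report(path: str, report: dict, dataset: str = "", seed: int = 0) -> None:
    """Key-value text report (one `key\tvalue` pair per line)."""
    with open(path, "w") as fh:
        fh.write(f"dataset\t{dataset}\nseed\t{seed}\n")
        for k, v in report.items():
            fh.write(f"{k}\t{v:.6f}\n")
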