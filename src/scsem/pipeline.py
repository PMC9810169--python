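"""End-to-end orchestration: read -> preprocess -> train -> cluster -> evaluate."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from scsem.clustering import ClusterResult, sem_to_affinity, spectral_cluster
from scsem.data import CountMatrix
from scsem.errors import ConfigError
from scsem.io import read_counts, read_labels
from scsem.metrics import metrics_report, write_metrics_report
from scsem.network import ModelConfig, train
from scsem.preprocess import preprocess

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str = ""
    input_format: str = "csv"
    orientation: str | None = None
    n_clusters: int = 2
    subspace_dim: int = 4
    n_hvg: int = 2000
    enhance: bool = True
    truth_labels: str | None = None
    outdir: str | None = None
    seed: int = 0
    save_affinity: bool = False
    save_checkpoint: bool = False
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.subspace_dim < 1:
            raise ConfigError("n_clusters and subspace_dim must be >= 1")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(rc: RunConfig, cm: CountMatrix | None = None):
    """Run the full clustering pipeline.

    ``cm`` may be passed directly (e.g. straight from the simulator);
    otherwise counts are read from ``rc.input_path``.  Returns
    ``(ClusterResult, metrics_dict_or_None, ModelState)``.
    """
    timings: dict[str, float] = {}
    t0 = time.time()
    if cm is None:
        cm = read_counts(rc.input_path, format=rc.input_format,
                         orientation=rc.orientation)
    timings["read"] = time.time() - t0

    rc.model.seed = rc.seed
    t0 = time.time()
    data = preprocess(cm, n_top=rc.n_hvg)
    timings["preprocess"] = time.time() - t0
    log.info("preprocessed: %d cells x %d genes", data.n_cells, data.n_genes)

    t0 = time.time()
    state = train(data, rc.model)
    timings["train"] = time.time() - t0

    t0 = time.time()
    affinity = sem_to_affinity(
        state.sem, subspace_dim=rc.subspace_dim, K=rc.n_clusters,
        enhance=rc.enhance,
    )
    result = spectral_cluster(
        affinity, K=rc.n_clusters, seed=rc.seed, subspace_dim=rc.subspace_dim,
    )
    timings["cluster"] = time.time() - t0

    report = None
    if rc.truth_labels:
        truth = read_labels(rc.truth_labels)
        truth = truth.loc[data.raw.cell_ids, "group"].to_numpy()
        report = metrics_report(truth, result.labels)
        log.info("metrics: %s", report)
    else:
        log.info("no truth labels supplied; metrics step skipped")

    if rc.outdir:
        _write_outputs(rc, data, state, result, report, timings)
    for stage, dt in timings.items():
        log.info("stage %-10s %.2fs", stage, dt)
    return result, report, state


def _write_outputs(rc, data, state, result, report, timings) -> None:
    os.makedirs(rc.outdir, exist_ok=True)
    pd.DataFrame(
        {"cell_id": data.raw.cell_ids, "label": result.labels}
    ).to_csv(os.path.join(rc.outdir, "labels.csv"), index=False)
    pd.DataFrame(state.loss_trace).to_csv(
        os.path.join(rc.outdir, "loss_trace.csv"), index=False
    )
    if rc.save_affinity:
        scipy.io.mmwrite(
            os.path.join(rc.outdir, "affinity.mtx"),
            scipy.sparse.coo_matrix(result.affinity),
        )
    if rc.save_checkpoint:
        state.save(os.path.join(rc.outdir, "checkpoint.npz"))
    if report is not None:
        write_metrics_report(
            os.path.join(rc.outdir, "metrics.tsv"), report,
            dataset=rc.input_path or "in-memory", seed=rc.seed,
        )
    manifest = {
        "config": rc.resolved(),
        "timings": timings,
        "n_cells": data.n_cells,
        "n_genes": data.n_genes,
    }
    with open(os.path.join(rc.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
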