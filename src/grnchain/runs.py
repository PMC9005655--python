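"""Run-directory conventions: self-describing, reproducible output folders.

Every command writes its outputs plus a ``run_config.json`` capturing all
parameters and seeds, so a run can be reproduced bit-for-bit from its own
directory.  A single user seed is fanned out to per-stage seeds through a
CRC-based derivation (stable across processes and platforms).
"""

from __future__ import annotations

import json
import os
import zlib

import numpy as np
import pandas as pd

from . import __version__
from .datasets import ExpressionDataset
from .inference import FitReport, IncidenceMatrixSet
from .synthetic import SyntheticTruth

BIAS_ROW = "__bias__"


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from one global seed."""
    return (int(seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def write_run_config(out_dir, config: dict) -> None:
    os.makedirs(out_dir, exist_ok=True)
    config = dict(config)
    config["tool_version"] = __version__
    with open(os.path.join(out_dir, "run_config.json"), "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)


def read_run_config(run_dir) -> dict:
    with open(os.path.join(run_dir, "run_config.json")) as fh:
        return json.load(fh)


# -- incidence matrices -----------------------------------------------------


def write_incidence_set(W_set: IncidenceMatrixSet, out_dir) -> None:
    """One TSV per phenotype (drivers + __bias__ rows x target columns) + sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    for k, (ph, frame) in enumerate(W_set.to_frames().items()):
        frame.index.name = "driver"
        frame.to_csv(os.path.join(out_dir, f"incidence_{k + 1}_{ph}.tsv"), sep="\t")
    sidecar = {
        "phenotype_order": W_set.phenotype_order,
        "lambda1": W_set.lambda1,
        "lambda2": W_set.lambda2,
    }
    with open(os.path.join(out_dir, "incidence.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_incidence_set(run_dir) -> IncidenceMatrixSet:
    with open(os.path.join(run_dir, "incidence.json")) as fh:
        sidecar = json.load(fh)
    order = sidecar["phenotype_order"]
    W_list, driver_ids, target_ids = [], None, None
    for k, ph in enumerate(order):
        frame = pd.read_csv(
            os.path.join(run_dir, f"incidence_{k + 1}_{ph}.tsv"), sep="\t", index_col=0
        )
        if driver_ids is None:
            driver_ids = [g for g in frame.index if g != BIAS_ROW]
            target_ids = list(frame.columns)
        W_list.append(frame.loc[driver_ids + [BIAS_ROW]].to_numpy(dtype=float))
    return IncidenceMatrixSet(
        W_list=W_list,
        driver_ids=driver_ids,
        target_ids=target_ids,
        phenotype_order=order,
        lambda1=sidecar["lambda1"],
        lambda2=sidecar["lambda2"],
    )


def write_fit_report(report: FitReport, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    summary = {
        "converged": report.converged,
        "n_epochs": report.n_epochs,
        "final_objective": report.objective_trace[-1] if report.objective_trace else None,
        "median_adjusted_r2": report.median_adjusted_r2,
    }
    with open(os.path.join(out_dir, "fit_report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    if report.adjusted_r2_per_target is not None:
        df = report.adjusted_r2_per_target.copy()
        df["pooled"] = report.adjusted_r2_pooled
        df.index.name = "target"
        df.to_csv(os.path.join(out_dir, "adjusted_r2.tsv"), sep="\t")
    if report.drivers_per_target is not None:
        d = report.drivers_per_target.copy()
        d.index.name = "target"
        d.to_csv(os.path.join(out_dir, "drivers_per_target.tsv"), sep="\t")


def write_truth(truth: SyntheticTruth, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for k, W in enumerate(truth.W_true_list):
        np.savetxt(
            os.path.join(out_dir, f"truth_state{k + 1}.tsv"), W, fmt="%d", delimiter="\t"
        )
    params = {
        "seed": truth.seed,
        "edge_probs": truth.edge_probs,
        "transition_probs": truth.transition_probs,
        "negbin_size": truth.negbin_size,
        "negbin_p": truth.negbin_p,
        "noise_sd": truth.noise_sd,
        "n_states": truth.n_states,
        "n_drivers": truth.n_drivers,
        "n_targets": truth.n_targets,
    }
    with open(os.path.join(out_dir, "truth_params.json"), "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)


def read_truth(run_dir) -> SyntheticTruth:
    with open(os.path.join(run_dir, "truth_params.json")) as fh:
        params = json.load(fh)
    W_list = [
        np.loadtxt(os.path.join(run_dir, f"truth_state{k + 1}.tsv"), delimiter="\t", ndmin=2)
        for k in range(params["n_states"])
    ]
    return SyntheticTruth(
        W_true_list=W_list,
        seed=params["seed"],
        edge_probs=params["edge_probs"],
        transition_probs=params["transition_probs"],
        negbin_size=params["negbin_size"],
        negbin_p=params["negbin_p"],
        noise_sd=params["noise_sd"],
    )


def load_dataset_from_run(run_dir, phenotype_order: list[str],
                          cells_as_rows: bool = False) -> ExpressionDataset:
    from .datasets import load_expression

    matrix = os.path.join(run_dir, "matrix.tsv")
    if not os.path.exists(matrix):
        matrix = os.path.join(run_dir, "matrix.mtx")
    return load_expression(
        matrix,
        os.path.join(run_dir, "metadata.tsv"),
        os.path.join(run_dir, "drivers.txt"),
        phenotype_order,
        cells_as_rows=cells_as_rows,
    )
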