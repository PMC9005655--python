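"""End-to-end drivers for the synthetic benchmark.

These wrap the generator, solver and evaluation metrics into the study
protocol: simulate the 5-state chain, hold out 20% of each state's cells,
fit joint networks on the training cells, and report (a) the mean held-out
adjusted R^2 across targets and states, (b) edge-recovery scores of the
thresholded networks against the ground truth, and (c) a reference fit of a
single network on all states pooled (which discards the state structure and
serves as the baseline the joint model is compared against).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, TrainTestSplit, split_train_test
from .inference import (
    DEFAULT_LAMBDA_GRID,
    IncidenceMatrixSet,
    SolverConfig,
    _blocks,
    _extend,
    _fit_blocks,
    adjusted_r2,
    cross_validate,
    fit_joint_grns,
)
from .synthetic import SyntheticTruth, cohens_kappa, generate_grn_chain, micro_f1, \
    simulate_expression, threshold_weights

__all__ = [
    "benchmark_data",
    "mean_test_adjusted_r2",
    "lambda2_sweep",
    "pooled_lasso",
    "edge_recovery",
]

#: the L1 strength held fixed while sweeping the fusion penalty
SWEEP_LAMBDA1 = 1e-2


def benchmark_data(seed: int, cells_per_state: int = 1000, **chain_kwargs):
    """Simulate the benchmark and split 80/20 per state; returns (truth, ds, split)."""
    truth = generate_grn_chain(seed=seed, **chain_kwargs)
    ds = simulate_expression(truth, cells_per_state=cells_per_state, seed=seed + 1)
    split = split_train_test(ds, 0.8, seed=seed + 2)
    return truth, ds, split


def mean_test_adjusted_r2(
    ds: ExpressionDataset, split: TrainTestSplit, W_set: IncidenceMatrixSet
) -> float:
    """Mean over targets and states of per-state held-out adjusted R^2.

    Each state's network predicts that state's test cells; p is the full
    driver count.
    """
    m = len(W_set.driver_ids)
    vals: list[float] = []
    for k, ph in enumerate(ds.phenotype_order):
        X = ds.driver_block(ph, split.test_cell_ids[ph])
        Y = ds.target_block(ph, split.test_cell_ids[ph])
        P = _extend(X) @ W_set.W_list[k]
        vals.extend(adjusted_r2(Y[:, j], P[:, j], m) for j in range(Y.shape[1]))
    return float(np.nanmean(vals))


def lambda2_sweep(
    ds: ExpressionDataset,
    split: TrainTestSplit,
    lambda2_values=(1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    lambda1: float = SWEEP_LAMBDA1,
    cfg: SolverConfig | None = None,
) -> pd.DataFrame:
    """Held-out fit quality as the fusion penalty grows, L1 strength fixed.

    Fits are warm-started along the sweep.  Returns one row per lambda2 with
    the mean held-out adjusted R^2.
    """
    cfg = cfg or SolverConfig()
    rows = []
    W_prev = None
    for lam2 in lambda2_values:
        W_set, _ = fit_joint_grns(ds, lambda1, lam2, cfg, cells=split.train_cell_ids,
                                  W0=W_prev)
        W_prev = W_set.W_list
        rows.append({"lambda2": lam2,
                     "mean_adjusted_r2": mean_test_adjusted_r2(ds, split, W_set)})
    return pd.DataFrame(rows)


def pooled_lasso(
    ds: ExpressionDataset,
    split: TrainTestSplit,
    lambda1: float = SWEEP_LAMBDA1,
    cfg: SolverConfig | None = None,
):
    """One network for all states pooled, scored on the combined test cells.

    Returns (W, mean adjusted R^2).  The single network is also the
    prediction for every state when computing edge-recovery baselines.
    """
    cfg = cfg or SolverConfig()
    X_list, Y_list = _blocks(ds, split.train_cell_ids)
    W_list, _, _ = _fit_blocks([np.vstack(X_list)], [np.vstack(Y_list)], lambda1, 0.0, cfg)
    W = W_list[0]
    m = len(ds.driver_ids)
    Xt = np.vstack([ds.driver_block(ph, split.test_cell_ids[ph]) for ph in ds.phenotype_order])
    Yt = np.vstack([ds.target_block(ph, split.test_cell_ids[ph]) for ph in ds.phenotype_order])
    P = _extend(Xt) @ W
    vals = [adjusted_r2(Yt[:, j], P[:, j], m) for j in range(Yt.shape[1])]
    return W, float(np.nanmean(vals))


def edge_recovery(
    truth: SyntheticTruth,
    ds: ExpressionDataset,
    lambdas: tuple[float, float] | None = None,
    threshold: float = 0.5,
    cv_folds: int = 5,
    seed: int = 0,
    cfg: SolverConfig | None = None,
) -> pd.DataFrame:
    """Cohen's kappa and micro-F1 of thresholded fitted networks per state.

    With ``lambdas=None`` the penalties are tuned by cross-validation over
    the default grid first; the final networks are fitted on all cells.
    """
    cfg = cfg or SolverConfig()
    if lambdas is None:
        l1, l2, _ = cross_validate(ds, DEFAULT_LAMBDA_GRID, DEFAULT_LAMBDA_GRID,
                                   folds=cv_folds, seed=seed, cfg=cfg)
    else:
        l1, l2 = lambdas
    W_set, _ = fit_joint_grns(ds, l1, l2, cfg)
    rows = []
    for k, ph in enumerate(ds.phenotype_order):
        pred = threshold_weights(W_set.W_list[k][:-1, :], threshold)
        rows.append({
            "phenotype": ph,
            "lambda1": l1,
            "lambda2": l2,
            "cohens_kappa": cohens_kappa(truth.W_true_list[k], pred),
            "micro_f1": micro_f1(truth.W_true_list[k], pred),
        })
    return pd.DataFrame(rows)
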