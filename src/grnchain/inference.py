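"""Joint inference of one regulatory network per ordered phenotype.

Model
-----
For each phenotype (cell state) k in a user-supplied linear order, target
expression is modelled as a linear function of driver (TF) expression,

    y_i = W^k^T x_i + b^k + eps_i,

and the K incidence matrices W^1..W^K are estimated jointly by minimising

    sum_k  1/(2 s_k) ||Y^k - X~^k W~^k||_F^2
         + lambda1 * sum_k |W^k|_1
         + lambda2 * sum_{k<K} ||W^k - W^{k+1}||_F^2,

where X~^k is X^k extended with a constant-1 column so that the bias b^k is
folded into the last row of W~^k.  The L1 term promotes sparse regulons; the
quadratic fusion term couples consecutive states so that networks change
smoothly along the phenotype ordering.  The data-fidelity term of each state
is scaled by its cell count s_k so that (a) states with unequal numbers of
cells carry equal weight and (b) the penalty strengths are on a per-cell
scale, independent of dataset size; ``loss_scale="total"`` gives the
unscaled sum-of-squares reading.

The bias row is exempt from both penalties by default (penalising an
intercept distorts the fit); ``penalize_bias=True`` restores the literal
folded-in reading.

Solver
------
Proximal block coordinate descent: each step picks a state k (cyclic by
default, uniformly random with ``block_schedule="random"``), takes a
gradient step on the smooth part (quadratic loss plus the fusion coupling
to neighbours k-1 and k+1) with step size 1/gamma_k, then applies the
entrywise soft-threshold prox of the L1 term with threshold lambda1/gamma_k.
gamma_k is the block Lipschitz constant: the largest eigenvalue of
X~^k^T X~^k (scaled by 1/s_k) plus the curvature 2*lambda2*deg(k) of the
fusion term, so the iteration is a descent method for every lambda2.
The objective is convex, so the zero initialisation is immaterial to the
optimum; it is used for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, TrainTestSplit, split_train_test

__all__ = [
    "IncidenceMatrixSet",
    "SolverConfig",
    "FitReport",
    "soft_threshold",
    "joint_objective",
    "fit_joint_grns",
    "predict_targets",
    "adjusted_r2",
    "assess_fit",
    "cross_validate",
]

NONZERO_TOL = 1e-8


@dataclass
class SolverConfig:
    """Solver settings for :func:`fit_joint_grns`."""

    max_epochs: int = 1000
    tol: float = 1e-5
    seed: int = 0
    block_schedule: str = "cyclic"  # or "random"
    penalize_bias: bool = False
    loss_scale: str = "per_cell"  # or "total"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.block_schedule not in ("cyclic", "random"):
            raise ValueError("block_schedule must be 'cyclic' or 'random'")
        if self.loss_scale not in ("per_cell", "total"):
            raise ValueError("loss_scale must be 'per_cell' or 'total'")


@dataclass
class IncidenceMatrixSet:
    """K fitted incidence matrices sharing gene indexing, one per phenotype.

    Each matrix has shape ``(m + 1, n)``: m driver rows plus a final bias
    row (label ``__bias__`` on disk).
    """

    W_list: list[np.ndarray]
    driver_ids: list[str]
    target_ids: list[str]
    phenotype_order: list[str]
    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        m, n = len(self.driver_ids), len(self.target_ids)
        for W in self.W_list:
            if W.shape != (m + 1, n):
                raise ValueError(f"incidence matrix shape {W.shape} != ({m + 1}, {n})")
        if len(self.W_list) != len(self.phenotype_order):
            raise ValueError("one matrix per phenotype required")

    @property
    def n_phenotypes(self) -> int:
        return len(self.W_list)

    def weights(self, phenotype: str) -> np.ndarray:
        """Driver x target weights for one phenotype, bias row dropped."""
        return self.W_list[self.phenotype_order.index(phenotype)][:-1, :]

    def bias(self, phenotype: str) -> np.ndarray:
        return self.W_list[self.phenotype_order.index(phenotype)][-1, :]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        index = list(self.driver_ids) + ["__bias__"]
        return {
            ph: pd.DataFrame(W, index=index, columns=self.target_ids)
            for ph, W in zip(self.phenotype_order, self.W_list)
        }


@dataclass
class FitReport:
    """Convergence trace and (optional) held-out goodness of fit."""

    objective_trace: list[float]
    converged: bool
    n_epochs: int
    adjusted_r2_per_target: pd.DataFrame | None = None  # targets x phenotypes
    adjusted_r2_pooled: pd.Series | None = None  # per target, test cells of all states
    median_adjusted_r2: float | None = None
    drivers_per_target: pd.DataFrame | None = None  # non-zero counts, targets x phenotypes


def soft_threshold(v, t):
    """Entrywise soft-thresholding ``sign(v) * max(|v| - t, 0)`` (prox of t*|.|_1)."""
    v = np.asarray(v, dtype=float)
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be non-negative")
    out = np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
    return float(out) if out.ndim == 0 else out


def _extend(X: np.ndarray) -> np.ndarray:
    """Append the constant-1 bias column."""
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _blocks(ds: ExpressionDataset, cells: dict[str, list[str]] | None):
    X_list, Y_list = [], []
    for ph in ds.phenotype_order:
        cid = None if cells is None else cells[ph]
        if cid is not None and len(cid) == 0:
            raise ValueError(f"phenotype {ph!r} has no cells")
        X = ds.driver_block(ph, cid)
        if X.shape[0] == 0:
            raise ValueError(f"phenotype {ph!r} has no cells")
        X_list.append(_extend(X))
        Y_list.append(ds.target_block(ph, cid))
    return X_list, Y_list


def _objective_from_grams(W_list, G_list, C_list, yty_list, scales, lambda1, lambda2,
                          penalize_bias):
    f = 0.0
    K = len(W_list)
    for k in range(K):
        W = W_list[k]
        quad = 0.5 * (np.sum(W * (G_list[k] @ W)) - 2.0 * np.sum(W * C_list[k]) + yty_list[k])
        f += scales[k] * quad
        pen = W if penalize_bias else W[:-1, :]
        f += lambda1 * np.sum(np.abs(pen))
    for k in range(K - 1):
        d = W_list[k] - W_list[k + 1]
        if not penalize_bias:
            d = d[:-1, :]
        f += lambda2 * np.sum(d * d)
    return f


def joint_objective(
    W_set: IncidenceMatrixSet,
    ds: ExpressionDataset,
    lambda1: float | None = None,
    lambda2: float | None = None,
    penalize_bias: bool = False,
    loss_scale: str = "per_cell",
) -> float:
    """Value of the joint objective for a given set of incidence matrices."""
    if lambda1 is None:
        lambda1 = W_set.lambda1
    if lambda2 is None:
        lambda2 = W_set.lambda2
    if W_set.phenotype_order != ds.phenotype_order:
        raise ValueError("phenotype order mismatch")
    if W_set.driver_ids != ds.driver_ids or W_set.target_ids != ds.target_ids:
        raise ValueError("gene indexing mismatch between dataset and incidence matrices")
    X_list, Y_list = _blocks(ds, None)
    f = 0.0
    K = len(X_list)
    for k in range(K):
        R = Y_list[k] - X_list[k] @ W_set.W_list[k]
        scale = 1.0 / X_list[k].shape[0] if loss_scale == "per_cell" else 1.0
        f += scale * 0.5 * np.sum(R * R)
        pen = W_set.W_list[k] if penalize_bias else W_set.W_list[k][:-1, :]
        f += lambda1 * np.sum(np.abs(pen))
    for k in range(K - 1):
        d = W_set.W_list[k] - W_set.W_list[k + 1]
        if not penalize_bias:
            d = d[:-1, :]
        f += lambda2 * np.sum(d * d)
    return float(f)


def _fit_blocks(
    X_list: list[np.ndarray],
    Y_list: list[np.ndarray],
    lambda1: float,
    lambda2: float,
    cfg: SolverConfig,
    W0: list[np.ndarray] | None = None,
):
    """Core proximal block coordinate descent on precomputed (bias-extended) blocks."""
    K = len(X_list)
    m1 = X_list[0].shape[1]  # m drivers + bias
    n = Y_list[0].shape[1]

    scales = [1.0 / X.shape[0] if cfg.loss_scale == "per_cell" else 1.0 for X in X_list]
    G_list = [X.T @ X for X in X_list]
    C_list = [X.T @ Y for X, Y in zip(X_list, Y_list)]
    yty_list = [float(np.sum(Y * Y)) for Y in Y_list]

    # drivers constant in every state are unidentifiable next to the bias: pin to 0
    zero_var = np.ones(m1 - 1, dtype=bool)
    for X in X_list:
        zero_var &= X[:, :-1].std(axis=0) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance driver(s); their weights are pinned to 0",
            stacklevel=3,
        )

    deg = [1 if k in (0, K - 1) and K > 1 else 2 for k in range(K)]
    if K == 1:
        deg = [0]
    gammas = []
    for k in range(K):
        lam_max = float(np.linalg.eigvalsh(G_list[k])[-1])
        gammas.append(scales[k] * lam_max + 2.0 * lambda2 * deg[k])

    if W0 is None:
        W_list = [np.zeros((m1, n)) for _ in range(K)]
    else:
        W_list = [W.copy() for W in W0]

    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    f_prev = _objective_from_grams(
        W_list, G_list, C_list, yty_list, scales, lambda1, lambda2, cfg.penalize_bias
    )
    trace.append(f_prev)
    converged = False
    for epoch in range(cfg.max_epochs):
        if cfg.block_schedule == "cyclic":
            order = range(K)
        else:
            order = rng.integers(0, K, size=K)
        for k in order:
            W = W_list[k]
            grad = scales[k] * (G_list[k] @ W - C_list[k])
            coup = np.zeros_like(W)
            if k > 0:
                coup += W - W_list[k - 1]
            if k < K - 1:
                coup += W - W_list[k + 1]
            if not cfg.penalize_bias:
                coup[-1, :] = 0.0
            grad += 2.0 * lambda2 * coup
            V = W - grad / gammas[k]
            thr = lambda1 / gammas[k]
            if cfg.penalize_bias:
                V = soft_threshold(V, thr)
            else:
                V[:-1, :] = soft_threshold(V[:-1, :], thr)
            if zero_var.any():
                V[:-1, :][zero_var, :] = 0.0
            W_list[k] = V
        f = _objective_from_grams(
            W_list, G_list, C_list, yty_list, scales, lambda1, lambda2, cfg.penalize_bias
        )
        if not np.isfinite(f):
            raise RuntimeError(
                "objective diverged (non-finite); increase the step denominator gamma_k "
                "or check the expression scale"
            )
        trace.append(f)
        if abs(f_prev - f) <= cfg.tol * max(1.0, abs(f_prev)):
            converged = True
            f_prev = f
            break
        f_prev = f
    return W_list, trace, converged


def fit_joint_grns(
    ds: ExpressionDataset,
    lambda1: float,
    lambda2: float,
    cfg: SolverConfig | None = None,
    cells: dict[str, list[str]] | None = None,
    W0: list[np.ndarray] | None = None,
) -> tuple[IncidenceMatrixSet, FitReport]:
    """Fit the K coupled incidence matrices.

    Parameters
    ----------
    cells
        Optional phenotype -> cell-id restriction (e.g. the training half of
        a split); default uses every cell of each phenotype.
    W0
        Optional warm start (e.g. the solution at a neighbouring penalty).
    """
    cfg = cfg or SolverConfig()
    if not all(np.isfinite(ds.matrix).ravel()):
        raise ValueError("expression matrix contains non-finite values")
    X_list, Y_list = _blocks(ds, cells)
    W_list, trace, converged = _fit_blocks(X_list, Y_list, lambda1, lambda2, cfg, W0)
    W_set = IncidenceMatrixSet(
        W_list=W_list,
        driver_ids=list(ds.driver_ids),
        target_ids=list(ds.target_ids),
        phenotype_order=list(ds.phenotype_order),
        lambda1=lambda1,
        lambda2=lambda2,
    )
    report = FitReport(objective_trace=trace, converged=converged, n_epochs=len(trace) - 1)
    return W_set, report


def predict_targets(W: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Linear prediction of target expression from driver expression.

    ``W`` is ``(m + 1, n)`` with the bias in the last row; ``X`` is cells x m.
    """
    W = np.asarray(W, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] + 1 != W.shape[0]:
        raise ValueError(f"X has {X.shape[1]} drivers but W expects {W.shape[0] - 1}")
    return _extend(X) @ W


def adjusted_r2(y_true, y_pred, p: int) -> float:
    """Adjusted coefficient of determination for a fit with ``p`` predictors.

    Returns NaN (flagged sentinel) when ``y_true`` has zero variance, where
    R^2 is undefined.  May be negative for fits worse than the mean.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    n_obs = y_true.size
    if n_obs < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} observations, got {n_obs}")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - p - 1)


def assess_fit(
    ds: ExpressionDataset,
    W_set: IncidenceMatrixSet,
    split: TrainTestSplit,
    report: FitReport | None = None,
) -> FitReport:
    """Held-out goodness of fit of fitted networks on the test cells of a split.

    Per target gene, predictions on each state's test cells (using that
    state's incidence matrix) are compared with the true expression both per
    phenotype and pooled across phenotypes; the number of predictors is the
    full driver count m.  The median (pooled) adjusted R^2 is the headline
    number.  Also counts non-zero driver weights per target and phenotype.
    """
    m = len(W_set.driver_ids)
    per_ph = {}
    counts = {}
    pooled_true = []
    pooled_pred = []
    for ph in ds.phenotype_order:
        test_cells = split.test_cell_ids[ph]
        X = ds.driver_block(ph, test_cells)
        Y = ds.target_block(ph, test_cells)
        W = W_set.W_list[ds.phenotype_order.index(ph)]
        Y_hat = predict_targets(W, X)
        pooled_true.append(Y)
        pooled_pred.append(Y_hat)
        per_ph[ph] = [adjusted_r2(Y[:, j], Y_hat[:, j], m) for j in range(Y.shape[1])]
        counts[ph] = (np.abs(W[:-1, :]) > NONZERO_TOL).sum(axis=0)
    Yc = np.vstack(pooled_true)
    Pc = np.vstack(pooled_pred)
    pooled = pd.Series(
        [adjusted_r2(Yc[:, j], Pc[:, j], m) for j in range(Yc.shape[1])],
        index=W_set.target_ids,
        name="adjusted_r2",
    )
    out = report or FitReport(objective_trace=[], converged=True, n_epochs=0)
    out.adjusted_r2_per_target = pd.DataFrame(per_ph, index=W_set.target_ids)
    out.adjusted_r2_pooled = pooled
    out.median_adjusted_r2 = float(np.nanmedian(pooled.to_numpy()))
    out.drivers_per_target = pd.DataFrame(counts, index=W_set.target_ids)
    return out


def cross_validate(
    ds: ExpressionDataset,
    grid1: list[float],
    grid2: list[float],
    folds: int = 5,
    seed: int = 0,
    cfg: SolverConfig | None = None,
    ratio: float = 0.8,
):
    """Select (lambda1, lambda2) by repeated stratified hold-out validation.

    Each of the ``folds`` repetitions draws a fresh stratified ``ratio``
    train/validation split (seeded), fits every grid pair on the training
    cells (warm-started along the grid) and scores the mean per-target
    adjusted R^2 on the validation cells.  Returns the pair with the best
    average validation score and the full table.
    """
    if not grid1 or not grid2:
        raise ValueError("empty hyperparameter grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cfg = cfg or SolverConfig()
    m = ds.n_drivers
    scores = np.zeros((len(grid1), len(grid2)))
    for f in range(folds):
        split = split_train_test(ds, ratio=ratio, seed=seed * folds + f)
        X_tr, Y_tr = _blocks(ds, split.train_cell_ids)
        X_va = [ds.driver_block(ph, split.test_cell_ids[ph]) for ph in ds.phenotype_order]
        Y_va = [ds.target_block(ph, split.test_cell_ids[ph]) for ph in ds.phenotype_order]
        for i, l1 in enumerate(grid1):
            W_prev = None
            for j, l2 in enumerate(grid2):
                W_list, _, _ = _fit_blocks(X_tr, Y_tr, l1, l2, cfg, W0=W_prev)
                W_prev = W_list
                Yc = np.vstack(Y_va)
                Pc = np.vstack([_extend(X) @ W for X, W in zip(X_va, W_list)])
                vals = [adjusted_r2(Yc[:, t], Pc[:, t], m) for t in range(Yc.shape[1])]
                scores[i, j] += float(np.nanmean(vals))
    scores /= folds
    best_i, best_j = np.unravel_index(int(np.argmax(scores)), scores.shape)
    table = pd.DataFrame(
        [
            {"lambda1": l1, "lambda2": l2, "mean_adjusted_r2": scores[i, j]}
            for i, l1 in enumerate(grid1)
            for j, l2 in enumerate(grid2)
        ]
    )
    return float(grid1[best_i]), float(grid2[best_j]), table


#: the hyperparameter grid used by default for both penalties
DEFAULT_LAMBDA_GRID = [1e-5, 1e-4, 1e-3, 1e-2, 1e-1]
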