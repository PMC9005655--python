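import functools

import numpy as np
import pytest

from grnchain import ExpressionDataset, generate_grn_chain, simulate_expression, split_train_test


def make_dataset(m=3, n=4, cells_per_state=30, K=2, seed=0, noise_sd=1.0):
    """Small linear-model dataset with known per-state weights (not ternary)."""
    rng = np.random.default_rng(seed)
    drivers = [f"TF{i}" for i in range(m)]
    targets = [f"G{j}" for j in range(n)]
    states = [f"s{k}" for k in range(K)]
    W_true = [rng.normal(0, 1, size=(m, n)) for _ in range(K)]
    X_parts, Y_parts, cells, phenos = [], [], [], {}
    for k, st in enumerate(states):
        X = rng.gamma(2.0, 2.0, size=(cells_per_state, m))
        Y = X @ W_true[k] + rng.normal(0, noise_sd, size=(cells_per_state, n))
        X_parts.append(X)
        Y_parts.append(Y)
        for c in range(cells_per_state):
            cid = f"{st}c{c}"
            cells.append(cid)
            phenos[cid] = st
    matrix = np.vstack([np.vstack(X_parts).T, np.vstack(Y_parts).T])
    ds = ExpressionDataset(
        matrix=matrix,
        gene_ids=drivers + targets,
        cell_ids=cells,
        phenotype_of_cell=phenos,
        phenotype_order=states,
        driver_ids=drivers,
        target_ids=targets,
    )
    return ds, W_true


@pytest.fixture
def tiny_ds():
    ds, _ = make_dataset(m=3, n=2, cells_per_state=25, K=2, seed=1)
    return ds


@functools.lru_cache(maxsize=4)
def benchmark_run(seed: int, cells_per_state: int = 1000):
    """Full-scale synthetic benchmark (5 states, 50 TFs, 20 targets) + 80/20 split."""
    truth = generate_grn_chain(seed=seed)
    ds = simulate_expression(truth, cells_per_state=cells_per_state, seed=seed + 10_000)
    split = split_train_test(ds, 0.8, seed=seed + 20_000)
    return truth, ds, split
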