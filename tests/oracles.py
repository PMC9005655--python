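"""Independent reference implementations used only to check the package.

These deliberately share no code with ``grnchain``: the LASSO oracle is a
plain cyclic coordinate-descent solver written against the textbook update
equations, and the HITS oracle extracts the principal eigenvector of A^T A
directly.
"""

from __future__ import annotations

import numpy as np


def lasso_cd(X, y, lam, max_iter=20000, tol=1e-13):
    """Cyclic coordinate descent for min_w,b 1/(2s)||y - Xw - b||^2 + lam*|w|_1.

    Returns (w, b).  The intercept is unpenalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    s, p = X.shape
    w = np.zeros(p)
    b = 0.0
    col_ss = (X * X).sum(axis=0) / s
    for _ in range(max_iter):
        w_old = w.copy()
        b_old = b
        r = y - X @ w - b
        b = b + r.mean()
        r = y - X @ w - b
        for j in range(p):
            if col_ss[j] == 0:
                w[j] = 0.0
                continue
            rho = (X[:, j] @ r) / s + col_ss[j] * w[j]
            wj_new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_ss[j]
            if wj_new != w[j]:
                r = r - X[:, j] * (wj_new - w[j])
                w[j] = wj_new
        if max(np.max(np.abs(w - w_old)), abs(b - b_old)) < tol:
            break
    return w, b


def lasso_cd_multi(X, Y, lam):
    """Column-by-column LASSO: returns a (p + 1, n) matrix with bias last row."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    p, n = X.shape[1], Y.shape[1]
    W = np.zeros((p + 1, n))
    for j in range(n):
        w, b = lasso_cd(X, Y[:, j], lam)
        W[:-1, j] = w
        W[-1, j] = b
    return W


def hits_eig(adjacency):
    """Authority/hub scores via direct eigendecomposition, max-normalised.

    ``adjacency`` is the (non-negative) drivers x targets weight matrix.
    Authority = principal eigenvector of A^T A, hub = principal eigenvector
    of A A^T, both scaled to unit maximum and made non-negative.
    """
    A = np.asarray(adjacency, dtype=float)
    ata = A.T @ A
    aat = A @ A.T
    wa, va = np.linalg.eigh(ata)
    wh, vh = np.linalg.eigh(aat)
    auth = np.abs(va[:, -1])
    hub = np.abs(vh[:, -1])
    return hub / hub.max(), auth / auth.max()
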