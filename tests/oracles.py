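"""Independent brute-force oracles used only by the test suite.

The grid-search REML oracle evaluates the restricted log-likelihood with
dense linear algebra over an explicit τ² grid — no profiling tricks, no
Woodbury identities — so it shares nothing with the implementation it
checks.
"""

from __future__ import annotations

import numpy as np


def restricted_loglik(tau2: float, y, v, study, X) -> float:
    """Dense-matrix restricted log-likelihood at a given τ² (up to constant)."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    study = np.asarray(study)
    labels = sorted(set(study.tolist()))
    Z = np.column_stack([(study == s).astype(float) for s in labels])
    V = np.diag(v) + tau2 * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetA = np.linalg.slogdet(A)
    return -0.5 * (logdetV + logdetA + r @ Vinv @ r)


def reml_grid_oracle(y, v, study, X=None, grid=None):
    """Maximize the restricted likelihood over an explicit τ² grid.

    Default grid: 0 … 1 in steps of 10⁻⁵. Returns (τ̂², β̂ at τ̂²).
    """
    y = np.asarray(y, dtype=float)
    if X is None:
        X = np.ones((len(y), 1))
    if grid is None:
        grid = np.arange(0.0, 1.0 + 1e-5, 1e-5)
    best_tau2, best_ll = 0.0, -np.inf
    for t2 in grid:
        ll = restricted_loglik(float(t2), y, v, study, X)
        if ll > best_ll:
            best_ll, best_tau2 = ll, float(t2)
    beta = gls_at_tau2(best_tau2, y, v, study, X)
    return best_tau2, beta


def gls_at_tau2(tau2: float, y, v, study, X):
    """Direct dense GLS coefficients at a fixed τ²."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    study = np.asarray(study)
    labels = sorted(set(study.tolist()))
    Z = np.column_stack([(study == s).astype(float) for s in labels])
    V = np.diag(v) + tau2 * (Z @ Z.T)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    return np.linalg.solve(A, X.T @ Vinv @ y)
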