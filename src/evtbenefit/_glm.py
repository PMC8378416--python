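"""Small internal GLM fitters (binary logistic, softmax regression).

Used by the calibration metrics and by regression imputation; kept
deliberately minimal (Newton / L-BFGS on analytic gradients, no inference
beyond what callers need).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """MLE of a binary logistic regression, optionally with a fixed offset.

    ``X`` must include an intercept column if one is wanted. Returns the
    coefficient vector. Newton-Raphson with step halving; a tiny ridge
    guards against separation-induced singular Hessians.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(p)

    def nll(b):
        z = X @ b + off
        # log(1 + exp(z)) - y*z, stable
        return float(np.sum(np.logaddexp(0.0, z) - y * z))

    current = nll(beta)
    for _ in range(max_iter):
        z = X @ beta + off
        mu = expit(z)
        g = X.T @ (y - mu)
        if np.max(np.abs(g)) <= tol * max(1.0, n):
            break
        w = mu * (1.0 - mu)
        H = X.T @ (w[:, None] * X) + 1e-10 * np.eye(p)
        step = np.linalg.solve(H, g)
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            val = nll(cand)
            if val <= current + 1e-12:
                beta, current = cand, val
                break
            t *= 0.5
        else:
            break
    return beta


def softmax_fit(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    """Multinomial-logistic coefficients, shape (n_classes - 1, p).

    Class 0 is the reference. ``y`` holds integer class codes 0..n_classes-1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    C = int(n_classes)
    Y = np.zeros((n, C))
    Y[np.arange(n), y] = 1.0

    def unpack(theta):
        B = np.zeros((C, p))
        B[1:] = theta.reshape(C - 1, p)
        return B

    def fun(theta):
        B = unpack(theta)
        Z = X @ B.T  # (n, C)
        lse = logsumexp(Z, axis=1)
        ll = np.sum(Z[np.arange(n), y] - lse)
        P = np.exp(Z - lse[:, None])
        G = (Y - P).T @ X  # (C, p)
        return -ll, -G[1:].ravel()

    res = minimize(fun, np.zeros((C - 1) * p), jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    return unpack(res.x)[1:]


def softmax_predict(X: np.ndarray, B_rest: np.ndarray) -> np.ndarray:
    """Most probable class under softmax coefficients from :func:`softmax_fit`."""
    X = np.asarray(X, dtype=float)
    C = B_rest.shape[0] + 1
    Z = np.zeros((X.shape[0], C))
    Z[:, 1:] = X @ B_rest.T
    return np.argmax(Z, axis=1)
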