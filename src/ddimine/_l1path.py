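"""Numba-accelerated L1-penalized logistic path solver.

Solves  min (1/n) sum logloss(y, b0 + X b) + lam * ||b||_1  (intercept
unpenalized) along a decreasing lambda path with warm starts, using the
iteratively-reweighted-least-squares + coordinate-descent scheme of the
glmnet family.  Soft-thresholding yields exact zeros, which downstream
sign-based interaction calls rely on.

The interaction inference fits this model tens of thousands of times on
five predictors over ~10^5 reports; a compiled coordinate-descent loop
keeps that tractable on one CPU.  Unit tests cross-check the solutions
against scikit-learn's liblinear solver.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["l1_logistic_path", "lambda_max"]


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes all slopes (KKT at the null model)."""
    y = np.asarray(y, dtype=np.float64)
    return float(np.abs(X.T @ (y - y.mean())).max() / y.size)


@njit(cache=True, fastmath=True)
def _path(X, y, lams, w_min, tol, max_outer, max_inner):  # pragma: no cover
    # IRLS with covariance updating: per quadratic approximation, build the
    # weighted Gram matrix of [1, X] once (O(n p^2)) so that each
    # coordinate-descent pass costs only O(p^2).
    n, p = X.shape
    L = lams.size
    betas = np.zeros((L, p))
    b0s = np.zeros(L)

    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return b0s, betas
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, b0)

    q = np.empty(p + 1)  # X_aug^T W z / n, coordinate 0 = intercept
    G = np.empty((p + 1, p + 1))  # X_aug^T W X_aug / n
    c = np.empty(p + 1)  # (b0, beta)

    for li in range(L):
        lam = lams[li]
        for _outer in range(max_outer):
            # quadratic approximation at the current linear predictor
            for k in range(p + 1):
                q[k] = 0.0
                for kk in range(p + 1):
                    G[k, kk] = 0.0
            for i in range(n):
                pi = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pi * (1.0 - pi)
                if wi < w_min:
                    wi = w_min
                zi = eta[i] + (y[i] - pi) / wi
                wz = wi * zi
                q[0] += wz
                G[0, 0] += wi
                for j in range(p):
                    xij = X[i, j]
                    q[j + 1] += wz * xij
                    wx = wi * xij
                    G[0, j + 1] += wx
                    for k in range(j, p):
                        G[j + 1, k + 1] += wx * X[i, k]
            for j in range(p + 1):  # symmetrize, scale by 1/n
                for k in range(j, p + 1):
                    G[j, k] /= n
                    G[k, j] = G[j, k]
                q[j] /= n

            c[0] = b0
            for j in range(p):
                c[j + 1] = beta[j]

            outer_delta = 0.0
            for _inner in range(max_inner):
                delta = 0.0
                for j in range(p + 1):
                    if G[j, j] <= 0.0:
                        continue
                    g = q[j]
                    for k in range(p + 1):
                        g -= G[j, k] * c[k]
                    u = g + G[j, j] * c[j]
                    if j == 0:  # intercept unpenalized
                        cj = u / G[j, j]
                    elif u > lam:
                        cj = (u - lam) / G[j, j]
                    elif u < -lam:
                        cj = (u + lam) / G[j, j]
                    else:
                        cj = 0.0
                    diff = cj - c[j]
                    if diff != 0.0:
                        c[j] = cj
                        if abs(diff) > delta:
                            delta = abs(diff)
                if delta > outer_delta:
                    outer_delta = delta
                if delta < tol:
                    break

            b0 = c[0]
            for j in range(p):
                beta[j] = c[j + 1]
            for i in range(n):
                s = b0
                for j in range(p):
                    s += X[i, j] * beta[j]
                eta[i] = s
            if outer_delta < tol:
                break
        b0s[li] = b0
        betas[li] = beta
    return b0s, betas


def l1_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lams: np.ndarray,
    w_min: float = 1e-5,
    tol: float = 1e-7,
    max_outer: int = 50,
    max_inner: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the warm-started path; returns (intercepts, slopes) per lambda.

    ``lams`` must be in decreasing order for warm starts to make sense.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lams = np.ascontiguousarray(lams, dtype=np.float64)
    if np.any(np.diff(lams) > 0):
        raise ValueError("lambda path must be non-increasing")
    return _path(X, y, lams, w_min, tol, max_outer, max_inner)
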