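"""G-BLUP with a single genomic random effect, and the marker-effect back-solve.

The mixed model is y = 1*mu + u + e with u ~ N(0, G sigma_u^2),
G = X X^T / L on -1/0/1 scores.  Variance components are estimated by
REML through a one-dimensional spectral (EMMA-style) profile over
delta = sigma_e^2 / sigma_u^2.  Marker effects are recovered from the
centered GEBVs as beta_hat = X^T (X X^T)^{-1} g_hat, which makes
X @ beta_hat reproduce g_hat exactly (up to solver precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import minimize_scalar

_RIDGE_COND = 1e12


@dataclass
class FittedGPModel:
    sigma_u2: float
    sigma_e2: float
    mu: float
    g_hat: np.ndarray
    beta_hat: np.ndarray


def backsolve_marker_effects(X: np.ndarray, g_hat: np.ndarray) -> np.ndarray:
    """beta_hat = X^T (X X^T)^{-1} g_hat, with a tiny ridge if X X^T is
    numerically ill-conditioned (cond > 1e12)."""
    X = np.asarray(X, dtype=float)
    XXt = X @ X.T
    cond = np.linalg.cond(XXt)
    if not np.isfinite(cond) or cond > _RIDGE_COND:
        XXt = XXt + (1e-8 * np.trace(XXt) / XXt.shape[0]) * np.eye(XXt.shape[0])
        if np.linalg.cond(XXt) > 1e14:
            raise np.linalg.LinAlgError("X X^T is rank deficient beyond ridge tolerance")
    return X.T @ np.linalg.solve(XXt, np.asarray(g_hat, dtype=float))


def gebv(X_new: np.ndarray, beta_hat: np.ndarray) -> np.ndarray:
    """GEBVs of (possibly later-generation) individuals: g = X_new @ beta_hat."""
    return np.asarray(X_new, dtype=float) @ np.asarray(beta_hat, dtype=float)


def fit_gblup(X: np.ndarray, y: np.ndarray) -> FittedGPModel:
    """Fit the single-kernel G-BLUP model by spectral REML.

    Requires N >= 10 individuals and at least as many markers as
    individuals (L >= N), so that the linear-kernel GRM is well formed
    and the back-solve identity holds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, L = X.shape
    if len(y) != N:
        raise ValueError("y length must match the number of rows of X")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if N < 10:
        raise ValueError(f"need at least 10 individuals, got {N}")
    if L < N:
        raise ValueError(f"need at least as many markers as individuals (L={L} < N={N})")

    G = X @ X.T / L
    if np.var(y) < 1e-12:
        return FittedGPModel(sigma_u2=0.0, sigma_e2=float(np.var(y)), mu=float(np.mean(y)),
                             g_hat=np.zeros(N), beta_hat=np.zeros(L))

    # Restricted likelihood: project out the intercept with an orthonormal
    # basis Q of the complement of 1, then profile over delta.
    Q = scipy.linalg.null_space(np.ones((1, N)))  # N x (N-1)
    A = Q.T @ G @ Q
    xi, U = np.linalg.eigh(A)
    xi = np.clip(xi, 0.0, None)
    eta = U.T @ (Q.T @ y)
    n_q = N - 1

    def neg_rll(log_delta: float) -> float:
        den = xi + np.exp(log_delta)
        s = np.sum(eta**2 / den)
        ll = 0.5 * (n_q * (np.log(n_q / (2 * np.pi)) - 1.0 - np.log(s)) - np.sum(np.log(den)))
        return -ll

    grid = np.linspace(-10.0, 10.0, 81)
    vals = np.array([neg_rll(g) for g in grid])
    if not np.all(np.isfinite(vals)):
        raise RuntimeError("REML profile is non-finite; check the genotype matrix")
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(neg_rll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"REML optimization did not converge: {res.message}")
    delta = float(np.exp(res.x))

    sigma_u2 = float(np.sum(eta**2 / (xi + delta)) / n_q)
    sigma_e2 = delta * sigma_u2
    V = sigma_u2 * G + sigma_e2 * np.eye(N)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_1 = np.linalg.solve(V, np.ones(N))
    mu = float(np.ones(N) @ Vinv_y / (np.ones(N) @ Vinv_1))
    g_hat = sigma_u2 * (G @ np.linalg.solve(V, y - mu))
    beta_hat = backsolve_marker_effects(X, g_hat)
    return FittedGPModel(sigma_u2=sigma_u2, sigma_e2=sigma_e2, mu=mu,
                         g_hat=g_hat, beta_hat=beta_hat)
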