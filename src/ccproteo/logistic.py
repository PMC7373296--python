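"""Maximum-likelihood logistic regression via Newton iteration.

A lean fitter tuned for the association scan, which refits the same small
design thousands of times (two nested models per protein per cohort).
Covariance is the inverse observed information at the MLE.  Separation is
not penalized (matching how wide the reported confidence intervals can
get in small case-control studies); fits with divergent coefficients are
flagged, not silently returned as significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelFit", "fit_logistic"]

#: |coefficient| above which (quasi-)separation is suspected
SEPARATION_BOUND = 15.0


@dataclass
class ModelFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    separation_suspected: bool
    names: list[str] | None = None
    n_iter: int = 0


def _loglike(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    names: list[str] | None = None,
) -> ModelFit:
    """Fit a binary logistic model by Newton-Raphson (IRLS).

    Converges on relative log-likelihood change below ``tol`` (default
    1e-8), at most ``max_iter`` iterations, with step halving when a full
    Newton step decreases the likelihood.  Raises on a one-class outcome
    or a rank-deficient design.  ``separation_suspected`` is set when the
    fit did not converge or any |coefficient| exceeds 15.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; logistic fit undefined")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll = _loglike(X, y, beta)
    converged = False
    it = 0
    hessian = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        score = X.T @ (y - mu)
        hessian = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError:
            break  # information matrix numerically singular: treat as separation
        new_beta = beta + step
        new_ll = _loglike(X, y, new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglike(X, y, new_beta)
            halvings += 1
        rel_change = abs(new_ll - ll) / (abs(ll) + 1.0)
        beta, ll = new_beta, new_ll
        if rel_change < tol:
            converged = True
            break

    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    hessian = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    separation = (not converged) or bool(np.max(np.abs(beta)) > SEPARATION_BOUND)
    return ModelFit(
        coefficients=beta,
        covariance=cov,
        log_likelihood=ll,
        converged=converged,
        separation_suspected=separation,
        names=names,
        n_iter=it,
    )
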