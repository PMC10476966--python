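"""Negative-binomial log-link GLM fitting by IRLS at fixed dispersion.

The NB2 parameterization is used throughout: for dispersion phi,
Var(Y) = mu + phi * mu^2 (size r = 1/phi). This module is the numerical
engine behind the interaction likelihood-ratio test and the Cox-Reid
dispersion estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

_ETA_CLAMP = 30.0  # bound on the linear predictor net of offsets


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood including all constant terms."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        raise ValueError("phi must be positive")
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu), where=y > 0, out=np.zeros_like(mu))
        )
    )


@dataclass
class NBFit:
    beta: np.ndarray
    mu: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


def check_full_rank(X: np.ndarray, colnames: list[str] | None = None) -> None:
    """Raise with the offending column names when X is rank deficient."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) >= p:
        return
    # identify columns beyond the rank via QR with column pivoting
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps
    bad = [piv[i] for i in range(p) if i >= len(diag) or diag[i] <= tol]
    names = (
        [colnames[i] for i in bad] if colnames is not None else [str(i) for i in bad]
    )
    raise np.linalg.LinAlgError(
        f"design matrix is rank deficient; confounded columns: {names}"
    )


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float,
    tol: float = 1e-8,
    max_iter: int = 100,
    beta0: np.ndarray | None = None,
) -> NBFit:
    """Fit log mu = offset + X beta by iteratively reweighted least squares.

    Converges when the relative change in log-likelihood drops below *tol*;
    step-halving guards against overshooting.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.asarray(offset, dtype=float)
    n, p = X.shape

    if beta0 is None:
        mu0 = y + 0.5
        z0 = np.log(mu0) - offset
        beta, *_ = np.linalg.lstsq(X, z0, rcond=None)
    else:
        beta = np.asarray(beta0, dtype=float).copy()

    def mu_of(b: np.ndarray) -> np.ndarray:
        eta = np.clip(X @ b, -_ETA_CLAMP, _ETA_CLAMP)
        return np.exp(offset + eta)

    mu = mu_of(beta)
    ll = nb_loglik(y, mu, phi)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu / (1.0 + phi * mu)  # IRLS working weights for NB log link
        z = np.clip(X @ beta, -_ETA_CLAMP, _ETA_CLAMP) + (y - mu) / mu
        Xw = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ z)
        except np.linalg.LinAlgError:
            break
        step = beta_new - beta
        # step-halving line search on the log-likelihood
        ll_new = nb_loglik(y, mu_of(beta + step), phi)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 20:
            step *= 0.5
            ll_new = nb_loglik(y, mu_of(beta + step), phi)
            halvings += 1
        beta = beta + step
        mu = mu_of(beta)
        if abs(ll_new - ll) <= tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    return NBFit(beta=beta, mu=mu, loglik=ll, converged=converged, n_iter=it)


def cr_adjusted_loglik(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float,
    beta0: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Cox-Reid adjusted profile log-likelihood at dispersion *phi*.

    Returns (APL, beta_hat); the adjustment subtracts
    0.5 * log det(X' W X) at the fitted coefficients.
    """
    fit = fit_nb_glm(y, X, offset, phi, beta0=beta0)
    w = fit.mu / (1.0 + phi * fit.mu)
    info = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        logdet = -np.inf
    return fit.loglik - 0.5 * logdet, fit.beta
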