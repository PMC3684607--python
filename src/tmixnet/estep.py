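"""Multivariate Student's-t densities, mixture likelihood and E-step moments.

The mixture treats each cluster k as a p-variate Student's-t with location
``mu_k``, inverse scale matrix ``omega_k`` (so the scale matrix is
``omega_k^{-1}``) and degrees of freedom ``nu_k``; ``nu_k = inf`` (or the
Gaussian family flag) recovers the multivariate normal.  All densities are
computed from the Cholesky factor of ``omega`` - the log-determinant comes
from the factor diagonal and the Mahalanobis distances from triangular
products, never from an explicit matrix inverse.

The latent variables are the component indicator z_i and, for t components,
a per-sample Gamma scale u_i with u_i | z_ik=1 ~ Gamma(nu_k/2, nu_k/2).
Conditional on the data and component, u_i ~ Gamma((nu_k+p)/2, (nu_k+d_ik)/2)
with d_ik the Mahalanobis squared distance, giving the closed-form
expectations computed by :func:`gamma_scale_moments`.
"""

from __future__ import annotations

import numpy as np
from numpy.linalg import LinAlgError, cholesky
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "component_pass",
    "t_logdensity",
    "mixture_loglik",
    "penalty_value",
    "penalized_objective",
    "responsibilities",
    "gamma_scale_moments",
]

_TAU_FLOOR = 1e-300


def component_pass(X: np.ndarray, mu: np.ndarray, omega: np.ndarray, nu: float):
    """One sufficient pass for a component: (log density, Mahalanobis^2).

    ``nu = inf`` gives the Gaussian log density.  Raises
    ``numpy.linalg.LinAlgError`` when ``omega`` is not positive definite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(omega, omega.T, atol=1e-8):
        raise ValueError("omega must be symmetric")
    L = cholesky(omega)  # omega = L @ L.T
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    y = (X - mu) @ L  # row i is L.T @ (x_i - mu)
    delta = np.einsum("ij,ij->i", y, y)
    if np.isinf(nu):
        logf = -0.5 * p * np.log(2.0 * np.pi) + 0.5 * logdet - 0.5 * delta
    else:
        if nu <= 0:
            raise ValueError("degrees of freedom must be positive")
        logf = (
            gammaln((nu + p) / 2.0)
            - gammaln(nu / 2.0)
            - 0.5 * p * np.log(np.pi * nu)
            + 0.5 * logdet
            - 0.5 * (nu + p) * np.log1p(delta / nu)
        )
    return logf, delta


def t_logdensity(x, mu, omega, nu) -> float:
    """Log density of a p-variate Student's t at a single point."""
    logf, _ = component_pass(np.atleast_2d(x), np.asarray(mu, float), omega, nu)
    return float(logf[0])


def _model_arrays(model):
    """Accept either a fitted estimator-like object or a tuple of arrays."""
    if isinstance(model, tuple):
        return model
    return (model.weights_, model.means_, model.precisions_, model.dofs_)


def _log_joint(X, weights, means, precisions, dofs):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    K = len(weights)
    logf = np.empty((n, K))
    delta = np.empty((n, K))
    for k in range(K):
        logf[:, k], delta[:, k] = component_pass(X, means[k], precisions[k], dofs[k])
    with np.errstate(divide="ignore"):
        logj = logf + np.log(np.asarray(weights, dtype=float))[None, :]
    return logj, delta


def mixture_loglik(X, model) -> float:
    """Observed-data log likelihood sum_i log sum_k pi_k f_k(x_i)."""
    weights, means, precisions, dofs = _model_arrays(model)
    if np.asarray(X).shape[1] != np.asarray(means).shape[1]:
        raise ValueError("dimension mismatch between data and model")
    logj, _ = _log_joint(X, weights, means, precisions, dofs)
    return float(logsumexp(logj, axis=1).sum())


def penalty_value(means, precisions, w_mu, w_omega, lambda1, lambda2) -> float:
    """Adaptive-L1 penalty of the objective: means plus upper-triangle precision."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty parameters must be nonnegative")
    means = np.asarray(means, float)
    precisions = np.asarray(precisions, float)
    pen = lambda1 * float(np.sum(np.asarray(w_mu) * np.abs(means)))
    p = precisions.shape[-1]
    iu = np.triu_indices(p, k=1)
    for k in range(precisions.shape[0]):
        pen += lambda2 * float(
            np.sum(np.asarray(w_omega)[k][iu] * np.abs(precisions[k][iu]))
        )
    return pen


def penalized_objective(X, model, w_mu, w_omega, lambda1, lambda2) -> float:
    """Penalized log likelihood: mixture_loglik minus the weighted L1 penalties."""
    weights, means, precisions, dofs = _model_arrays(model)
    return mixture_loglik(X, model) - penalty_value(
        means, precisions, w_mu, w_omega, lambda1, lambda2
    )


def responsibilities(X, model):
    """Posterior membership probabilities tau (n x K), rows summing to 1."""
    weights, means, precisions, dofs = _model_arrays(model)
    logj, delta = _log_joint(X, weights, means, precisions, dofs)
    tau = np.exp(logj - logsumexp(logj, axis=1, keepdims=True))
    tau = np.maximum(tau, _TAU_FLOOR)
    tau /= tau.sum(axis=1, keepdims=True)
    return tau


def gamma_scale_moments(delta: np.ndarray, dofs, p: int):
    """Conditional Gamma-scale moments for each (sample, component).

    uhat    = (nu + p) / (nu + delta)
    loguhat = digamma((nu + p)/2) - log((nu + delta)/2)

    For Gaussian components (``nu = inf``) the scale is degenerate at 1:
    uhat = 1, loguhat = 0.
    """
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    dofs = np.asarray(dofs, dtype=float)
    uhat = np.empty_like(delta)
    loguhat = np.empty_like(delta)
    for k, nu in enumerate(dofs):
        if np.isinf(nu):
            uhat[:, k] = 1.0
            loguhat[:, k] = 0.0
        else:
            uhat[:, k] = (nu + p) / (nu + delta[:, k])
            loguhat[:, k] = digamma((nu + p) / 2.0) - np.log((nu + delta[:, k]) / 2.0)
    return uhat, loguhat


def e_step(X, weights, means, precisions, dofs):
    """Full E-step: (tau, uhat, loguhat, loglik)."""
    X = np.asarray(X, dtype=float)
    logj, delta = _log_joint(X, weights, means, precisions, dofs)
    lse = logsumexp(logj, axis=1, keepdims=True)
    tau = np.exp(logj - lse)
    tau = np.maximum(tau, _TAU_FLOOR)
    tau /= tau.sum(axis=1, keepdims=True)
    uhat, loguhat = gamma_scale_moments(delta, dofs, X.shape[1])
    return tau, uhat, loguhat, float(lse.sum())
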