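"""M-step updates for the penalized t-mixture.

Per EM iteration the updates are, in order: mixing proportions (closed form),
penalized means (cyclic coordinate ascent with soft thresholding), weighted
scatter and precision matrices (weighted graphical lasso), and degrees of
freedom (bracketed 1-D root of the expected complete-data score).

Family behaviour:
  * ``pmt-uc`` - t components, unconstrained (penalized) precisions;
  * ``pmg-uc`` - Gaussian components (``uhat`` fixed at 1, ``nu`` ignored),
    unconstrained penalized precisions;
  * ``pmt-dc`` - t components, diagonal precisions ``omega_jj = 1/S_jj``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.special import digamma

from . import wglasso

__all__ = [
    "AdaptiveWeights",
    "update_pi",
    "update_nu",
    "adaptive_weights",
    "update_mu",
    "weighted_scatter",
    "update_precision",
    "DegenerateComponentError",
]


class DegenerateComponentError(RuntimeError):
    """A mixture component has (numerically) collapsed to zero mass."""


@dataclass(frozen=True)
class AdaptiveWeights:
    """Adaptive-lasso weights 1/(|initial estimate| + epsilon).

    ``w_mu`` has shape (K, p); ``w_omega`` shape (K, p, p), symmetric with the
    diagonal ignored (the precision diagonal is never penalized).
    """

    w_mu: np.ndarray
    w_omega: np.ndarray

    def __post_init__(self):
        if (self.w_mu <= 0).any() or (self.w_omega <= 0).any():
            raise ValueError("adaptive weights must be strictly positive")

    @classmethod
    def unit(cls, K: int, p: int) -> "AdaptiveWeights":
        """Plain (unweighted) L1 penalty, used for the preliminary fit."""
        return cls(np.ones((K, p)), np.ones((K, p, p)))


def adaptive_weights(mu_tilde, omega_tilde, epsilon: float) -> AdaptiveWeights:
    """Weights from a preliminary estimate: w = 1 / (|theta~| + epsilon).

    ``epsilon`` keeps the weights finite so that a coefficient shrunk to zero
    in the preliminary fit can still escape zero.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    w_mu = 1.0 / (np.abs(np.asarray(mu_tilde, float)) + epsilon)
    w_omega = 1.0 / (np.abs(np.asarray(omega_tilde, float)) + epsilon)
    w_omega = 0.5 * (w_omega + np.swapaxes(w_omega, -1, -2))
    return AdaptiveWeights(w_mu, w_omega)


def update_pi(tau: np.ndarray, min_mass: float | None = None) -> np.ndarray:
    """Mixing proportions pi_k = mean_i tau_ik.

    Raises :class:`DegenerateComponentError` when a component's mass falls
    below ``min_mass`` (default 1/(10 n)).
    """
    tau = np.asarray(tau, dtype=float)
    n = tau.shape[0]
    pi = tau.mean(axis=0)
    if min_mass is None:
        min_mass = 1.0 / (10.0 * n)
    if (pi < min_mass).any():
        raise DegenerateComponentError(
            f"component mass below {min_mass:.3g}: pi={np.round(pi, 6)}"
        )
    return pi / pi.sum()


def update_nu(tau_k, uhat_k, loguhat_k, nu_old: float, p: int, bounds=(2.001, 200.0)) -> float:
    """Degrees-of-freedom update: root of the expected complete-data score.

    Solves, over nu in ``bounds``,

        -digamma(nu/2) + log(nu/2) + 1
            + sum_i tau_ik (loguhat_ik - uhat_ik) / sum_i tau_ik = 0.

    ``loguhat`` is the conditional expectation E[log u | x, z] (which already
    carries the digamma((nu_old+p)/2) - log((nu_old+p)/2) correction relative
    to log(uhat), so the customary explicit correction term is built in).
    The left side is decreasing in nu; when it has no root in the bracket the
    nearer bound is returned with a warning (the upper bound means
    "effectively Gaussian").
    """
    lo, hi = bounds
    if lo <= 2.0:
        raise ValueError("lower degrees-of-freedom bound must exceed 2")
    tau_k = np.asarray(tau_k, float)
    mass = tau_k.sum()
    if mass <= 0:
        raise DegenerateComponentError("empty component in nu update")
    c = float(np.sum(tau_k * (np.asarray(loguhat_k) - np.asarray(uhat_k))) / mass)

    def score(nu):
        return -digamma(nu / 2.0) + np.log(nu / 2.0) + 1.0 + c

    s_lo, s_hi = score(lo), score(hi)
    if s_lo <= 0.0:
        warnings.warn("nu update clamped at lower bound", RuntimeWarning)
        return float(lo)
    if s_hi >= 0.0:
        # moments are Gaussian-consistent: effectively infinite df
        return float(hi)
    return float(brentq(score, lo, hi, xtol=1e-6))


@njit(cache=True)
def _mu_cd(omega, om_m, T, pen, mu, tol, max_sweeps):
    """Cyclic coordinate ascent for the L1-penalized weighted quadratic.

    Maximizes mu' (omega @ m) - (T/2) mu' omega mu - sum_j pen_j |mu_j|,
    where m = sum_i tau*uhat*x_i and T = sum_i tau*uhat.
    """
    p = mu.shape[0]
    q = omega @ mu  # maintained = omega @ mu
    for _ in range(max_sweeps):
        dmax = 0.0
        for j in range(p):
            a = T * omega[j, j]
            b = om_m[j] - T * (q[j] - omega[j, j] * mu[j])
            if abs(b) <= pen[j]:
                new = 0.0
            elif b > 0.0:
                new = (b - pen[j]) / a
            else:
                new = (b + pen[j]) / a
            d = new - mu[j]
            if d != 0.0:
                for l in range(p):
                    q[l] += omega[l, j] * d
                ad = abs(d)
                if ad > dmax:
                    dmax = ad
                mu[j] = new
        if dmax < tol:
            break
    return mu


def update_mu(X, tau_k, uhat_k, omega_k, w_mu_k, lambda1, mu_current,
              tol: float = 1e-6, max_sweeps: int = 100) -> np.ndarray:
    """Penalized mean update by cyclic coordinate ascent.

    Each coordinate solves a scalar quadratic-plus-L1 problem: with
    ``a_j = omega_jj * sum tau*uhat`` and ``b_j`` the coordinate's residualized
    linear term, ``mu_j = 0`` when ``|b_j| <= lambda1 * w_j``, otherwise the
    soft-thresholded value ``sign(b_j)(|b_j| - lambda1 w_j)/a_j``.
    """
    X = np.asarray(X, float)
    tu = np.asarray(tau_k, float) * np.asarray(uhat_k, float)
    T = float(tu.sum())
    if T <= 0:
        raise DegenerateComponentError("empty component in mean update")
    omega_k = np.ascontiguousarray(omega_k, dtype=float)
    if (np.diag(omega_k) <= 0).any():
        raise ValueError("precision diagonal must be positive")
    m = tu @ X
    om_m = omega_k @ m
    pen = np.ascontiguousarray(lambda1 * np.asarray(w_mu_k, float))
    mu = np.ascontiguousarray(np.array(mu_current, dtype=float, copy=True))
    return _mu_cd(omega_k, om_m, T, pen, mu, tol, max_sweeps)


def weighted_scatter(X, tau_k, uhat_k, mu_k) -> np.ndarray:
    """Posterior-weighted scatter S~ = sum tau*uhat (x-mu)(x-mu)' / sum tau."""
    X = np.asarray(X, float)
    tau_k = np.asarray(tau_k, float)
    mass = tau_k.sum()
    if mass <= 0:
        raise DegenerateComponentError("empty component in scatter update")
    Xc = X - np.asarray(mu_k, float)
    tu = tau_k * np.asarray(uhat_k, float)
    S = (Xc * tu[:, None]).T @ Xc / mass
    return 0.5 * (S + S.T)


def update_precision(S_tilde, w_omega_k, lambda2, n_eff, family: str = "pmt-uc",
                     tol: float = 1e-5, max_iter: int = 500):
    """Precision update.

    For the unconstrained families this is the weighted graphical lasso on
    ``S_tilde`` with penalty matrix ``P = (lambda2 / n_eff) * w_omega`` off the
    diagonal (the scaling that makes the update an exact maximization of the
    EM surrogate of the penalized likelihood, whose precision penalty counts
    each unordered pair once).  For ``pmt-dc`` the precision is diagonal,
    ``omega_jj = 1 / S_jj``.
    """
    S_tilde = np.asarray(S_tilde, float)
    if (np.diag(S_tilde) < 1e-10).any():
        raise DegenerateComponentError(
            "component scatter has a zero-variance gene (component collapsed)"
        )
    if family == "pmt-dc":
        return np.diag(1.0 / np.diag(S_tilde))
    if n_eff <= 0:
        raise DegenerateComponentError("empty component in precision update")
    P = (lambda2 / n_eff) * np.asarray(w_omega_k, float)
    np.fill_diagonal(P, 0.0)
    omega, _ = wglasso.solve(S_tilde, P, tol=tol, max_iter=max_iter)
    return omega
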