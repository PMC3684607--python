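"""Penalized robust mixture estimator.

:class:`PenalizedTMixture` fits a K-component multivariate Student's-t (or
Gaussian) mixture by EM, with adaptive L1 penalties on the component means
and on the off-diagonal entries of the cluster-specific inverse scale
matrices (solved by a weighted graphical lasso in the M-step).  Zeros in the
fitted means mark genes that do not discriminate between clusters; zeros in a
fitted precision encode conditional independence, so each component's
precision doubles as a sparse gene network.

Fitting runs ``n_restarts`` independent K-means initializations; each restart
first runs EM with the plain (unit-weight) L1 penalty, then freezes the
adaptive weights 1/(|theta~|+epsilon) at that preliminary solution and
re-runs EM, and the restart with the highest final penalized objective wins.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from numpy.linalg import LinAlgError
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from . import estep, mstep
from .data import ExpressionMatrix
from .mstep import AdaptiveWeights, DegenerateComponentError

__all__ = [
    "PenalizedTMixture",
    "initialize_params",
    "effective_params",
    "awe",
    "predict_clusters",
    "FAMILIES",
]

logger = logging.getLogger(__name__)

FAMILIES = ("pmt-uc", "pmg-uc", "pmt-dc")

_MONOTONE_SLACK = 1e-6


def _as_array(X):
    if isinstance(X, ExpressionMatrix):
        return X.values
    if hasattr(X, "to_numpy"):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def initialize_params(X, K: int, seed: int, family: str = "pmt-uc",
                      nu_init: float = 10.0, var_floor: float = 1e-4,
                      n_init: int = 1):
    """K-means initialization: hard labels give pi, mu, diagonal omega, nu.

    ``n_init`` controls how many k-means++ runs the label search uses; the
    EM driver uses a best-inertia run for its first restart and single
    random runs for the remaining restarts, so that restarts explore
    genuinely different basins.  Re-seeds up to 10 times if K-means returns
    an empty cluster.
    """
    X = _as_array(X)
    n, p = X.shape
    if K > n:
        raise ValueError("more components than samples")
    for attempt in range(10):
        km = KMeans(n_clusters=K, n_init=n_init,
                    random_state=(seed + attempt) % (2**31))
        labels = km.fit_predict(X)
        counts = np.bincount(labels, minlength=K)
        if counts.min() > 0:
            break
    else:
        raise RuntimeError("K-means produced an empty cluster in 10 attempts")
    pi = counts / n
    mu = np.stack([X[labels == k].mean(axis=0) for k in range(K)])
    omega = np.zeros((K, p, p))
    for k in range(K):
        var = X[labels == k].var(axis=0)
        np.fill_diagonal(omega[k], 1.0 / np.maximum(var, var_floor))
    if family == "pmg-uc":
        nu = np.full(K, np.inf)
    else:
        nu = np.full(K, float(nu_init))
    return pi, mu, omega, nu


def effective_params(model) -> int:
    """Effective parameter count d for the AWE criterion.

    d = (K-1) mixing proportions
        + K degrees-of-freedom terms (t families only)
        + number of nonzero mean entries
        + K*p precision diagonals
        + number of nonzero off-diagonal precision entries / 2
          (unconstrained families only; diagonal family has none).
    """
    K, p = model.means_.shape
    d = (K - 1) + np.count_nonzero(model.means_) + K * p
    if model.family in ("pmt-uc", "pmt-dc"):
        d += K
    if model.family != "pmt-dc":
        for k in range(K):
            off = model.precisions_[k].copy()
            np.fill_diagonal(off, 0.0)
            d += np.count_nonzero(off) // 2
    return int(d)


def classification_loglik(model, X) -> float:
    """Hard-assignment (classification) log likelihood L_c."""
    X = _as_array(X)
    logj, _ = estep._log_joint(
        X, model.weights_, model.means_, model.precisions_, model.dofs_
    )
    z = np.argmax(logj, axis=1)
    return float(logj[np.arange(X.shape[0]), z].sum())


def awe(model, X) -> float:
    """Approximate weight of evidence: -2 L_c + 2 d (3/2 + log n); lower is better."""
    X = _as_array(X)
    n = X.shape[0]
    d = effective_params(model)
    return -2.0 * classification_loglik(model, X) + 2.0 * d * (1.5 + np.log(n))


def predict_clusters(model, X) -> np.ndarray:
    """MAP cluster labels (ties broken toward the lowest component index)."""
    tau = estep.responsibilities(_as_array(X), model)
    return np.argmax(tau, axis=1)


class _Params:
    __slots__ = ("weights_", "means_", "precisions_", "dofs_")

    def __init__(self, pi, mu, omega, nu):
        self.weights_, self.means_, self.precisions_, self.dofs_ = pi, mu, omega, nu

    def astuple(self):
        return (self.weights_, self.means_, self.precisions_, self.dofs_)


class PenalizedTMixture(ClusterMixin, BaseEstimator):
    """Penalized model-based Student's-t clustering with sparse networks.

    Parameters
    ----------
    n_components : int
        Number of mixture components K.
    lambda1, lambda2 : float
        Nonnegative penalty strengths for the means and for the off-diagonal
        precision entries, respectively.
    family : {"pmt-uc", "pmg-uc", "pmt-dc"}
        t components with unconstrained precisions (the full method), the
        Gaussian variant, or the t variant with diagonal precisions.
    epsilon : float
        Stabilizer of the adaptive weights 1/(|theta~| + epsilon).
    adaptive : bool
        If True (default) run the two-stage plain-L1 -> adaptive-L1 fit;
        if False only the plain-L1 stage is run.
    tol : float
        Relative change of the penalized objective for EM convergence.
    max_iter : int
        EM iteration cap per stage.
    n_restarts : int
        Independent K-means restarts of the whole procedure.
    nu_bounds : (float, float)
        Search bracket for the degrees of freedom; the lower bound must
        exceed 2 so component covariances exist.  Hitting the upper bound
        means "effectively Gaussian".
    nu_init : float
        Initial degrees of freedom for t families.
    max_edges_factor : float
        Sparsity guard: a restart is treated as degenerate when a component's
        precision acquires more than ``max_edges_factor * p`` off-diagonal
        nonzero pairs.  With fewer samples than genes an almost-dense
        precision means the penalty is too weak to control the fit and the
        likelihood is running away; such restarts carry no information.
    random_state : int or None
        Seed for the restarts.

    Attributes
    ----------
    weights_, means_, precisions_, dofs_ : fitted component parameters.
    responsibilities_ : (n, K) posterior memberships on the training data.
    labels_ : MAP training labels.
    objective_trace_ : penalized-objective values of the winning adaptive run.
    awe_ : model-selection criterion on the training data.
    effective_params_ : nonzero-parameter census used by ``awe_``.
    converged_ : whether the winning run met ``tol`` before ``max_iter``.
    """

    def __init__(self, n_components=2, lambda1=0.0, lambda2=0.0, family="pmt-uc",
                 epsilon=0.1, adaptive=True, tol=1e-6, max_iter=500, n_restarts=5,
                 nu_bounds=(2.001, 200.0), nu_init=10.0, glasso_tol=1e-5,
                 max_edges_factor=3.0, random_state=None):
        self.n_components = n_components
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.family = family
        self.epsilon = epsilon
        self.adaptive = adaptive
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.nu_bounds = nu_bounds
        self.nu_init = nu_init
        self.glasso_tol = glasso_tol
        self.max_edges_factor = max_edges_factor
        self.random_state = random_state

    # ------------------------------------------------------------------ EM

    def _em(self, X, params: _Params, weights: AdaptiveWeights):
        """Run EM from ``params`` with fixed penalty weights.

        Returns (params, trace, converged).  Raises
        :class:`DegenerateComponentError` if a component collapses.
        """
        n, p = X.shape
        K = self.n_components
        trace = []
        converged = False
        pi, mu, omega, nu = (params.weights_.copy(), params.means_.copy(),
                             params.precisions_.copy(), params.dofs_.copy())
        t_family = self.family != "pmg-uc"
        for it in range(self.max_iter):
            tau, uhat, loguhat, loglik = estep.e_step(X, pi, mu, omega, nu)
            obj = loglik - estep.penalty_value(
                mu, omega, weights.w_mu, weights.w_omega, self.lambda1, self.lambda2
            )
            if trace:
                rel = (obj - trace[-1]) / (1.0 + abs(trace[-1]))
                if rel < -_MONOTONE_SLACK:
                    logger.warning("objective decreased by %.3e at iter %d", -rel, it)
                trace.append(obj)
                if abs(rel) < self.tol:
                    converged = True
                    break
            else:
                trace.append(obj)
            pi = mstep.update_pi(tau)
            n_eff = tau.sum(axis=0)
            for k in range(K):
                mu[k] = mstep.update_mu(
                    X, tau[:, k], uhat[:, k], omega[k], weights.w_mu[k],
                    self.lambda1, mu[k],
                )
                S = mstep.weighted_scatter(X, tau[:, k], uhat[:, k], mu[k])
                omega[k] = mstep.update_precision(
                    S, weights.w_omega[k], self.lambda2, n_eff[k],
                    family=self.family, tol=self.glasso_tol,
                )
                if self.max_edges_factor is not None and self.family != "pmt-dc":
                    n_pairs = (np.count_nonzero(omega[k]) - p) // 2
                    if n_pairs > self.max_edges_factor * p:
                        raise DegenerateComponentError(
                            f"component {k} precision nearly dense "
                            f"({n_pairs} edge pairs); penalty too weak"
                        )
                if t_family:
                    nu[k] = mstep.update_nu(
                        tau[:, k], uhat[:, k], loguhat[:, k], nu[k], p,
                        self.nu_bounds,
                    )
        return _Params(pi, mu, omega, nu), trace, converged

    def _fit_one_restart(self, X, seed: int, n_init: int = 1):
        K, p = self.n_components, X.shape[1]
        init = initialize_params(
            X, K, seed, family=self.family, nu_init=self.nu_init, n_init=n_init
        )
        params = _Params(*(np.asarray(a, dtype=float) for a in init))
        unit = AdaptiveWeights.unit(K, p)
        if (self.lambda1 == 0 and self.lambda2 == 0) or not self.adaptive:
            params, trace, conv = self._em(X, params, unit)
            return params, unit, trace, conv
        params, _, _ = self._em(X, params, unit)
        w = mstep.adaptive_weights(params.means_, params.precisions_, self.epsilon)
        params, trace, conv = self._em(X, params, w)
        return params, w, trace, conv

    # ----------------------------------------------------------------- API

    def fit(self, X, y=None):
        Xarr = _as_array(X)
        if isinstance(X, ExpressionMatrix) and not X.standardized:
            raise ValueError("fit expects gene-standardized expression data")
        if Xarr.ndim != 2 or not np.isfinite(Xarr).all():
            raise ValueError("X must be a finite 2-D array")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be nonnegative")
        if self.nu_bounds[0] <= 2.0:
            raise ValueError("nu lower bound must exceed 2")
        base = 0 if self.random_state is None else int(self.random_state)
        best = None
        failures = []
        for r in range(self.n_restarts):
            seed = int(
                np.random.SeedSequence([base, r]).generate_state(1, np.uint32)[0]
                % (2**31)
            )
            try:
                params, w, trace, conv = self._fit_one_restart(Xarr, seed, n_init=10)
            except (DegenerateComponentError, LinAlgError) as exc:
                logger.info("restart %d discarded: %s", r, exc)
                failures.append(str(exc))
                continue
            if best is None or trace[-1] > best[2][-1]:
                best = (params, w, trace, conv)
        if best is None:
            raise RuntimeError(
                f"all {self.n_restarts} restarts degenerated: {failures}"
            )
        params, w, trace, conv = best
        self.weights_, self.means_, self.precisions_, self.dofs_ = params.astuple()
        self.penalty_weights_ = w
        self.objective_trace_ = trace
        self.converged_ = bool(conv)
        self.n_iter_ = len(trace)
        self.responsibilities_ = estep.responsibilities(Xarr, self)
        self.labels_ = np.argmax(self.responsibilities_, axis=1)
        self.effective_params_ = effective_params(self)
        self.awe_ = awe(self, Xarr)
        self.n_features_in_ = Xarr.shape[1]
        if isinstance(X, ExpressionMatrix):
            self.gene_ids_ = X.gene_ids
        return self

    def predict_proba(self, X):
        return estep.responsibilities(_as_array(X), self)

    def predict(self, X):
        return predict_clusters(self, X)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def score_samples(self, X):
        from scipy.special import logsumexp

        logj, _ = estep._log_joint(
            _as_array(X), self.weights_, self.means_, self.precisions_, self.dofs_
        )
        return logsumexp(logj, axis=1)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))
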