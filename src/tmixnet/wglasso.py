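"""Weighted graphical lasso: sparse precision estimation with an elementwise penalty.

Maximizes

    log det(Omega) - tr(S Omega) - sum_{j != l} P[j, l] * |Omega[j, l]|

over symmetric positive-definite ``Omega``, where ``S`` is a (weighted) scatter
matrix and ``P`` a symmetric, nonnegative penalty matrix with unpenalized
diagonal.  The sum runs over both triangles, so each unordered gene pair is
penalized with weight ``2 * P[j, l]``.

The solver is the classic block-coordinate descent of the graphical lasso
(each row/column update is a lasso subproblem on the current covariance
estimate ``W``), preceded by the exact connected-component screening rule:
``Omega`` is block diagonal across the connected components of the graph
``|S[j, l]| > P[j, l]``, so each component can be solved independently and
isolated genes reduce to ``omega_jj = 1 / S_jj``.  Inner loops are compiled
with numba.

``reference_solve`` is an independent proximal-gradient solver for small
problems, used as a testing oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.csgraph import connected_components

__all__ = ["solve", "reference_solve", "wglasso_objective", "duality_gap", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when the solver exhausts its iteration budget."""


def _check_inputs(S: np.ndarray, P: np.ndarray):
    S = np.asarray(S, dtype=float)
    P = np.asarray(P, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if P.shape != S.shape:
        raise ValueError("P must have the same shape as S")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("S must be symmetric")
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("P must be symmetric")
    if (P < 0).any():
        raise ValueError("P must be nonnegative")
    if (np.diag(S) <= 0).any():
        raise ValueError("S has a nonpositive diagonal (zero-variance coordinate)")
    return S, P


@njit(cache=True)
def _soft(x, t):
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _glasso_block(S, P, tol, max_iter):
    """Dense BCD graphical lasso on one screened block.

    Returns (W, Omega, n_sweeps, converged).
    """
    p = S.shape[0]
    W = S.copy()
    B = np.zeros((p, p))  # column j holds beta for row/column j
    off_mean = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                off_mean += abs(S[i, j])
                cnt += 1
    off_mean = off_mean / cnt if cnt else 0.0
    thr = tol * off_mean if off_mean > 0 else tol
    converged = False
    sweeps = 0
    g = np.zeros(p)  # residual W11 @ beta, maintained incrementally
    for it in range(max_iter):
        sweeps = it + 1
        delta = 0.0
        for j in range(p):
            # lasso subproblem on W11 (all rows/cols except j)
            beta = B[:, j]
            for m in range(p):
                val = 0.0
                for l in range(p):
                    if l != j:
                        val += W[m, l] * beta[l]
                g[m] = val
            for inner in range(100):
                dmax = 0.0
                for m in range(p):
                    if m == j:
                        continue
                    z = S[m, j] - (g[m] - W[m, m] * beta[m])
                    b_new = _soft(z, P[m, j]) / W[m, m]
                    d = b_new - beta[m]
                    if d != 0.0:
                        for l in range(p):
                            g[l] += W[l, m] * d
                        beta[m] = b_new
                        ad = abs(d)
                        if ad > dmax:
                            dmax = ad
                if dmax < 1e-8:
                    break
            # w12 = W11 @ beta = g (excluding index j)
            for m in range(p):
                if m == j:
                    continue
                delta += abs(g[m] - W[m, j])
                W[m, j] = g[m]
                W[j, m] = g[m]
        if cnt == 0 or delta / cnt < thr:
            converged = True
            break
    Omega = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for m in range(p):
            if m != j:
                dot += W[m, j] * B[m, j]
        ojj = 1.0 / (W[j, j] - dot)
        Omega[j, j] = ojj
        for m in range(p):
            if m != j:
                Omega[m, j] = -B[m, j] * ojj
    # symmetrize
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (Omega[i, j] + Omega[j, i])
            # preserve exact zeros produced by the soft threshold
            if Omega[i, j] == 0.0 or Omega[j, i] == 0.0:
                v = 0.0
            Omega[i, j] = v
            Omega[j, i] = v
    return W, Omega, sweeps, converged


def wglasso_objective(omega: np.ndarray, S: np.ndarray, P: np.ndarray) -> float:
    """Penalized log-det objective (both triangles penalized)."""
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    off = omega - np.diag(np.diag(omega))
    return logdet - float(np.sum(S * omega)) - float(np.sum(P * np.abs(off)))


def duality_gap(omega: np.ndarray, S: np.ndarray, P: np.ndarray) -> float:
    """Duality gap certificate tr(S Omega) - p + sum_{j!=l} P|omega_jl|."""
    off = omega - np.diag(np.diag(omega))
    return float(np.sum(S * omega) - S.shape[0] + np.sum(P * np.abs(off)))


def solve(S, P, tol: float = 1e-5, max_iter: int = 500):
    """Solve the weighted graphical lasso.

    Parameters
    ----------
    S : (p, p) symmetric PSD scatter matrix.
    P : (p, p) symmetric nonnegative penalty matrix (diagonal ignored).
    tol : float
        Termination when the mean absolute change of the off-diagonal of the
        working covariance per sweep drops below ``tol * mean|S_offdiag|``,
        or the duality gap falls below ``tol``.
    max_iter : int
        Maximum BCD sweeps per screened block.

    Returns
    -------
    omega : (p, p) symmetric positive-definite precision estimate with exact
        zeros at strongly penalized entries.
    cov : (p, p) the covariance estimate maintained by the sweeps.
    """
    S, P = _check_inputs(S, P)
    p = S.shape[0]
    omega = np.zeros((p, p))
    cov = np.zeros((p, p))

    # exact screening: block structure of the solution
    adj = np.abs(S) > P
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        sparse.csr_matrix(adj), directed=False
    )
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        if idx.size == 1:
            j = idx[0]
            omega[j, j] = 1.0 / S[j, j]
            cov[j, j] = S[j, j]
            continue
        Sb = np.ascontiguousarray(S[np.ix_(idx, idx)])
        Pb = np.ascontiguousarray(P[np.ix_(idx, idx)])
        if not Pb[~np.eye(idx.size, dtype=bool)].any():
            # unpenalized block: optimum is the plain inverse
            c_fac = cho_factor(Sb)
            Ob = cho_solve(c_fac, np.eye(idx.size))
            Ob = 0.5 * (Ob + Ob.T)
            Wb = Sb
        else:
            Wb, Ob, sweeps, ok = _glasso_block(Sb, Pb, tol, max_iter)
            if not ok:
                gap = duality_gap(Ob, Sb, Pb)
                if abs(gap) > tol:
                    raise ConvergenceError(
                        f"graphical lasso failed to converge on a {idx.size}-gene "
                        f"block after {max_iter} sweeps (duality gap {gap:.3e})"
                    )
        omega[np.ix_(idx, idx)] = Ob
        cov[np.ix_(idx, idx)] = Wb
    return omega, cov


def reference_solve(S, P, gap_tol: float = 1e-8, max_iter: int = 100_000):
    """Slow proximal-gradient oracle for small instances (p <= 8).

    Independent of the block-coordinate path: FISTA (accelerated proximal
    gradient with function-value restart) on the smooth part
    ``-log det Omega + tr(S Omega)`` with elementwise off-diagonal soft
    thresholding, run until the stationarity certificate
    ``|tr(S Omega) - p + sum P|omega||`` is below ``gap_tol``.  Used for
    cross-solver agreement tests only.
    """
    S, P = _check_inputs(S, P)
    p = S.shape[0]
    if p > 8:
        raise ValueError("reference_solve is restricted to p <= 8")
    Pod = P.copy()
    np.fill_diagonal(Pod, 0.0)

    def prox_step(M, t):
        cand = np.sign(M) * np.maximum(np.abs(M) - t * Pod, 0.0)
        ii = np.arange(p)
        cand[ii, ii] = M[ii, ii]  # diagonal unpenalized
        return 0.5 * (cand + cand.T)

    omega = np.diag(1.0 / np.diag(S))
    ymat = omega.copy()
    t_mom = 1.0
    step = 1.0 / max(np.linalg.eigvalsh(S).max(), 1.0) ** 2
    obj = wglasso_objective(omega, S, P)
    for _ in range(max_iter):
        if np.all(np.linalg.eigvalsh(ymat) > 1e-12):
            grad_pt = ymat
        else:
            grad_pt = omega
        grad = S - np.linalg.inv(grad_pt)
        t = step
        for _bt in range(60):
            cand = prox_step(grad_pt - t * grad, t)
            if np.all(np.linalg.eigvalsh(cand) > 0):
                break
            t *= 0.5
        new_obj = wglasso_objective(cand, S, P)
        if new_obj < obj:  # restart momentum on objective decrease
            t_mom = 1.0
            ymat = omega.copy()
            step = max(step * 0.5, 1e-8)
            continue
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        ymat = cand + ((t_mom - 1.0) / t_next) * (cand - omega)
        omega, obj, t_mom = cand, new_obj, t_next
        if abs(duality_gap(omega, S, P)) < gap_tol:
            break
        step = min(step * 1.2, 1e3)
    return omega
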