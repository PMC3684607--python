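"""Model selection: AWE grid search over (K, lambda1, lambda2).

The approximate weight of evidence

    AWE = -2 L_c + 2 d (3/2 + log n)

(classification log likelihood L_c at the hard MAP assignment, effective
parameter count d) penalizes complexity more heavily than BIC; the grid
search fits every triple in the Cartesian product of the grids and keeps the
fit with the smallest AWE.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .mixture import PenalizedTMixture

__all__ = ["AWESearch", "grid_search"]

logger = logging.getLogger(__name__)


class AWESearch(ClusterMixin, BaseEstimator):
    """Fit :class:`PenalizedTMixture` over a grid and select by minimum AWE.

    Parameters mirror :class:`PenalizedTMixture` except that ``K_grid``,
    ``lambda1_grid`` and ``lambda2_grid`` replace the scalar settings.  Each
    grid cell gets its own deterministic seed derived from ``random_state``.

    Attributes
    ----------
    best_estimator_ : the argmin-AWE fitted mixture.
    best_params_ : dict with the selected K, lambda1, lambda2.
    results_ : DataFrame with one row per triple
        (K, lambda1, lambda2, d, L_c, AWE, converged).
    labels_ : training labels of the best fit.
    """

    def __init__(self, K_grid=(2, 3, 4, 5), lambda1_grid=(0.0,), lambda2_grid=(0.0,),
                 family="pmt-uc", epsilon=0.1, adaptive=True, tol=1e-6, max_iter=500,
                 n_restarts=5, nu_bounds=(2.001, 200.0), nu_init=10.0,
                 glasso_tol=1e-5, random_state=None):
        self.K_grid = K_grid
        self.lambda1_grid = lambda1_grid
        self.lambda2_grid = lambda2_grid
        self.family = family
        self.epsilon = epsilon
        self.adaptive = adaptive
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.nu_bounds = nu_bounds
        self.nu_init = nu_init
        self.glasso_tol = glasso_tol
        self.random_state = random_state

    def fit(self, X, y=None):
        if not (len(self.K_grid) and len(self.lambda1_grid) and len(self.lambda2_grid)):
            raise ValueError("all grids must be non-empty")
        from .mixture import classification_loglik

        rows = []
        best = None
        base = 0 if self.random_state is None else int(self.random_state)
        cells = list(itertools.product(self.K_grid, self.lambda1_grid, self.lambda2_grid))
        for idx, (K, l1, l2) in enumerate(cells):
            seed = int(
                np.random.SeedSequence([base, 7919 + idx]).generate_state(1, np.uint32)[0]
                % (2**31)
            )
            model = PenalizedTMixture(
                n_components=K, lambda1=l1, lambda2=l2, family=self.family,
                epsilon=self.epsilon, adaptive=self.adaptive, tol=self.tol,
                max_iter=self.max_iter, n_restarts=self.n_restarts,
                nu_bounds=self.nu_bounds, nu_init=self.nu_init,
                glasso_tol=self.glasso_tol, random_state=seed,
            )
            try:
                model.fit(X)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning("grid cell (K=%d, l1=%g, l2=%g) failed: %s", K, l1, l2, exc)
                rows.append(dict(K=K, lambda1=l1, lambda2=l2, d=np.nan,
                                 L_c=np.nan, AWE=np.nan, converged=False))
                continue
            Lc = classification_loglik(model, X)
            rows.append(dict(K=K, lambda1=l1, lambda2=l2, d=model.effective_params_,
                             L_c=Lc, AWE=model.awe_, converged=model.converged_))
            if best is None or model.awe_ < best.awe_:
                best = model
        self.results_ = pd.DataFrame(rows)
        if best is None:
            raise RuntimeError("every grid cell failed to fit")
        self.best_estimator_ = best
        self.best_params_ = dict(
            K=best.n_components, lambda1=best.lambda1, lambda2=best.lambda2
        )
        self.labels_ = best.labels_
        self.awe_ = best.awe_
        return self

    def predict(self, X):
        return self.best_estimator_.predict(X)

    def predict_proba(self, X):
        return self.best_estimator_.predict_proba(X)


def grid_search(X, config: AWESearch = None, **kwargs):
    """Functional wrapper: returns (best fitted mixture, selection table)."""
    search = config if config is not None else AWESearch(**kwargs)
    search.fit(X)
    return search.best_estimator_, search.results_
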