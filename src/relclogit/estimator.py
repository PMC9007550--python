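"""Scikit-learn style estimator facade over the estimation core.

`RELCLogit` exposes the model through the familiar fit / predict_proba /
transform surface so it composes with sklearn model-selection utilities;
the X argument of the sklearn API is a :class:`~relclogit.data.RankingDataset`
(choice data are panel-structured, not a flat feature matrix).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import RankingDataset
from .estimation import FitConfig, fit as _fit
from .posterior import class_posteriors

__all__ = ["RELCLogit"]


class RELCLogit(BaseEstimator):
    """Random effects latent class logit for ranked choice data.

    Parameters mirror :class:`~relclogit.estimation.FitConfig` plus the model
    dimensions: ``n_classes`` latent preference classes and ``n_effects``
    standard-normal random effects tied to attribute domains.

    Attributes (after fit)
    ----------------------
    params_ : RELCLParams
        Canonicalized maximum-likelihood estimates.
    loglik_, bic_, n_params_ : float / int
        Fit statistics (BIC uses ``bic_sample_size``).
    converged_ : bool
    result_ : FitResult
        Full result including per-start diagnostics.
    """

    def __init__(
        self,
        n_classes: int = 1,
        n_effects: int = 0,
        em_iterations: int = 250,
        newton_iterations: int = 50,
        n_starts: int = 16,
        tol: float = 1e-4,
        seed: int = 0,
        n_nodes: int = 7,
        integration: str = "gauss-hermite",
        n_draws: int = 200,
        mstep_maxiter: int = 25,
        beta_start_sd: float = 0.5,
        order_constraint: bool = True,
        bic_sample_size: str = "participants",
        standard_errors: bool = False,
    ):
        self.n_classes = n_classes
        self.n_effects = n_effects
        self.em_iterations = em_iterations
        self.newton_iterations = newton_iterations
        self.n_starts = n_starts
        self.tol = tol
        self.seed = seed
        self.n_nodes = n_nodes
        self.integration = integration
        self.n_draws = n_draws
        self.mstep_maxiter = mstep_maxiter
        self.beta_start_sd = beta_start_sd
        self.order_constraint = order_constraint
        self.bic_sample_size = bic_sample_size
        self.standard_errors = standard_errors

    def _config(self) -> FitConfig:
        return FitConfig(
            em_iterations=self.em_iterations,
            newton_iterations=self.newton_iterations,
            n_starts=self.n_starts,
            tol=self.tol,
            seed=self.seed,
            n_nodes=self.n_nodes,
            integration=self.integration,
            n_draws=self.n_draws,
            mstep_maxiter=self.mstep_maxiter,
            beta_start_sd=self.beta_start_sd,
            order_constraint=self.order_constraint,
            bic_sample_size=self.bic_sample_size,
            standard_errors=self.standard_errors,
        )

    def fit(self, X: RankingDataset, y=None) -> "RELCLogit":
        if not isinstance(X, RankingDataset):
            raise TypeError("X must be a RankingDataset")
        self.result_ = _fit(
            X, X.scheme, self.n_classes, self.n_effects, self._config()
        )
        self.params_ = self.result_.params
        self.loglik_ = self.result_.loglik
        self.bic_ = self.result_.bic
        self.n_params_ = self.result_.n_params
        self.converged_ = self.result_.converged
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError("call fit first")

    def predict_proba(self, X: RankingDataset) -> np.ndarray:
        """Posterior class-membership probabilities (n, X)."""
        self._check_fitted()
        return class_posteriors(self.result_, X).probs

    def predict(self, X: RankingDataset) -> np.ndarray:
        """Modal (0-based) class assignment."""
        return self.predict_proba(X).argmax(axis=1)

    def transform(self, X: RankingDataset) -> np.ndarray:
        """Posterior-mean random-effect scores (n, D)."""
        self._check_fitted()
        return class_posteriors(self.result_, X).F_mean

    def score(self, X: RankingDataset, y=None) -> float:
        """Average marginal log-likelihood per participant."""
        from .likelihood import marginal_loglik

        self._check_fitted()
        grid = self._config().make_grid(self.params_.n_effects)
        return marginal_loglik(self.params_, X, grid) / X.n_participants
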