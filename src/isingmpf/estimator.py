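"""Scikit-learn style estimator facade over the MPF / Partial-MPF machinery.

``MPFIsing`` is a density estimator for binary trait matrices: rows are
entities, columns are YES(+1)/NO(-1) questions, NaN marks an unknown answer.
It fits the pairwise maximum-entropy (inverse Ising) landscape by minimum
probability flow, switching automatically to the partial-data objective when
unknowns are present, and plays by the sklearn rules (``get_params`` /
``set_params``, trailing-underscore fitted attributes, ``clone``-ability), so
it can sit inside pipelines and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .core import IsingParameters, log_partition
from .data import ObservationSet
from .mpf import MPFSettings, NeighborhoodSpec, fit_mpf
from .model_selection import heldout_loglik
from .partial import completion_weights, fit_partial_mpf


class MPFIsing(BaseEstimator):
    """Inverse Ising landscape estimator via minimum probability flow.

    Parameters
    ----------
    alpha : float, default 0.0
        L2 regularization strength (the lambda of the penalized objective,
        scaled by total weight times neighbourhood size).
    neighborhood_order : {1, 2}, default 1
        Flow neighbourhoods: single flips (N1) or up to double flips (N2).
    include_data_states : bool, default True
        Allow flow into states that appear elsewhere in the data.
    tol, max_iter :
        L-BFGS stopping controls (projected-gradient tolerance, iteration cap).
    max_missing : int, default 10
        Cap on unknown answers per row (2^m completions are enumerated).
    fit_mode : {"joint", "alternating"}, default "joint"
        Joint differentiation through the completion weights, or EM-style
        alternation (comparison only).

    Attributes
    ----------
    params_ : IsingParameters
    couplings_, fields_ : ndarray views of the fitted parameters
    objective_value_, converged_, n_iter_, lambda_used_ : fit diagnostics
    """

    def __init__(
        self,
        alpha: float = 0.0,
        neighborhood_order: int = 1,
        include_data_states: bool = True,
        tol: float = 1e-8,
        max_iter: int = 2000,
        max_missing: int = 10,
        fit_mode: str = "joint",
    ):
        self.alpha = alpha
        self.neighborhood_order = neighborhood_order
        self.include_data_states = include_data_states
        self.tol = tol
        self.max_iter = max_iter
        self.max_missing = max_missing
        self.fit_mode = fit_mode

    def _settings(self) -> MPFSettings:
        return MPFSettings(
            neighborhood=NeighborhoodSpec(
                order=self.neighborhood_order,
                include_data_states=self.include_data_states,
            ),
            lam=self.alpha,
            tol=self.tol,
            max_iter=self.max_iter,
        )

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        known = X[~np.isnan(X)]
        if not np.all(np.isin(known, (-1.0, 1.0))):
            raise ValueError("X entries must be +1, -1, or NaN (unknown)")
        return X

    def fit(self, X, y=None, sample_weight=None):
        """Fit the landscape; X is (m, n) with entries +1 / -1 / NaN."""
        X = self._validate(X)
        obs = ObservationSet.from_array(X, weights=sample_weight)
        settings = self._settings()
        if obs.has_missing:
            result = fit_partial_mpf(
                obs, settings, mode=self.fit_mode, max_missing=self.max_missing
            )
        else:
            result = fit_mpf(obs, settings)
        self.params_ = result.params
        self.couplings_ = result.params.couplings
        self.fields_ = result.params.fields
        self.objective_value_ = result.objective_value
        self.converged_ = result.converged
        self.n_iter_ = result.n_iterations
        self.lambda_used_ = result.lambda_used
        self.n_features_in_ = obs.n
        return self

    def log_probability(self, X) -> np.ndarray:
        """Exact normalized log-probability per row (marginal over NaNs)."""
        check_is_fitted(self, "params_")
        X = self._validate(X)
        log_z = log_partition(self.params_)
        return np.array(
            [
                heldout_loglik(
                    self.params_, row, log_z=log_z, max_missing=self.max_missing
                )
                for row in X
            ]
        )

    def score(self, X, y=None, sample_weight=None) -> float:
        """Mean (weighted) held-out log-likelihood; higher is better."""
        ll = self.log_probability(X)
        if sample_weight is None:
            return float(ll.mean())
        w = np.asarray(sample_weight, dtype=float)
        return float(ll @ w / w.sum())

    def conditional(self, x):
        """Completion distribution for one partial row (see landscape module
        for the ranked-table presentation)."""
        check_is_fitted(self, "params_")
        return completion_weights(
            self.params_, np.asarray(x, dtype=float), max_missing=self.max_missing
        )

    def sample(self, n_samples: int, random_state=None, burn_in_sweeps: int = 2000,
               thin_sweeps: int = 10) -> np.ndarray:
        """Draw configurations from the fitted landscape (Metropolis-Hastings)."""
        check_is_fitted(self, "params_")
        from .simulate import metropolis_sample

        rng = np.random.default_rng(random_state)
        return metropolis_sample(
            self.params_, n_samples, rng,
            burn_in_sweeps=burn_in_sweeps, thin_sweeps=thin_sweeps,
        )
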