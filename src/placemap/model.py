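"""scikit-learn style estimator wrapping the sparse coding network."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .network import ModelConfig, NetworkState, fit_dictionary, lca_infer_batch

__all__ = ["SparseCodingPlaceMap"]


def _as_generator(random_state) -> np.random.Generator:
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


class SparseCodingPlaceMap(TransformerMixin, BaseEstimator):
    """Non-negative sparse coding model of the entorhinal-hippocampal map.

    ``fit(X)`` learns a non-negative dictionary over the columns of ``X``
    (rows = spatial locations, columns = entorhinal cells) by online
    presentations of single rows; ``transform(X)`` returns the sparse
    hippocampal rates obtained by running the locally competitive dynamics
    to (approximate) convergence for each row.

    Parameters
    ----------
    n_hippocampal : int, default 100
        Number of hippocampal units (dictionary columns).
    tau_ms, beta, dt_ms, n_steps : float/int
        Membrane time constant (ms), firing threshold, Euler step (ms) and
        number of integration steps per presentation.
    eta : float, default 0.03
        Online learning rate.
    n_epochs : int, default 20000
        Number of single-location presentations.
    noise_amp : float, default 0
        SD of additive Gaussian response noise during training.
    random_state : int, Generator or None
        Seeds dictionary initialization, location sampling and noise.

    Attributes
    ----------
    A_ : ndarray of shape (n_features, n_hippocampal)
        Learned dictionary; non-negative with unit-norm columns.
    W_ : ndarray of shape (n_hippocampal, n_hippocampal)
        Lateral competition matrix ``A_^T A_ - I``.
    components_ : ndarray of shape (n_hippocampal, n_features)
        ``A_.T``, following the sklearn decomposition convention.
    training_log_ : pandas.DataFrame
        Sampled (epoch, cost, active_fraction) during training.
    """

    def __init__(
        self,
        n_hippocampal: int = 100,
        tau_ms: float = 10.0,
        beta: float = 0.3,
        dt_ms: float = 0.8,
        n_steps: int = 200,
        eta: float = 0.03,
        n_epochs: int = 20000,
        noise_amp: float = 0.0,
        random_state=None,
    ):
        self.n_hippocampal = n_hippocampal
        self.tau_ms = tau_ms
        self.beta = beta
        self.dt_ms = dt_ms
        self.n_steps = n_steps
        self.eta = eta
        self.n_epochs = n_epochs
        self.noise_amp = noise_amp
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            tau_ms=self.tau_ms,
            beta=self.beta,
            dt_ms=self.dt_ms,
            n_steps=self.n_steps,
            eta=self.eta,
            n_epochs=self.n_epochs,
            n_hippocampal=self.n_hippocampal,
            noise_amp=self.noise_amp,
        )

    def fit(self, X, y=None, location_sequence: Optional[Sequence[int]] = None):
        """Learn the dictionary from location-indexed responses ``X``."""
        X = check_array(X, dtype=float)
        rng = _as_generator(self.random_state)
        state = fit_dictionary(
            X, self._config(), rng, location_sequence=location_sequence
        )
        self.n_features_in_ = X.shape[1]
        self.A_ = state.A
        self.W_ = state.W
        self.components_ = state.A.T
        self.training_log_ = state.training_log
        self.n_dead_units_ = state.n_dead_respawns
        return self

    @property
    def state_(self) -> NetworkState:
        check_is_fitted(self, "A_")
        return NetworkState(A=self.A_, W=self.W_)

    def transform(self, X) -> np.ndarray:
        """Sparse hippocampal rates for each row of ``X``."""
        check_is_fitted(self, "A_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with "
                f"{self.n_features_in_}"
            )
        return lca_infer_batch(self.state_, X, self._config())

    def inverse_transform(self, S) -> np.ndarray:
        """Reconstruct entorhinal responses from hippocampal rates."""
        check_is_fitted(self, "A_")
        S = check_array(S, dtype=float)
        return S @ self.components_
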