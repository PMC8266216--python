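"""Non-negative sparse coding network: inference dynamics and learning.

The entorhinal-to-hippocampal mapping is a dictionary ``A`` (one unit-norm,
non-negative column per hippocampal cell).  Given an entorhinal response
``s_e``, hippocampal rates solve the non-negative, l1-penalized sparse
coding problem

    min_{s >= 0}  1/2 ||s_e - A s||^2 + beta * sum(s)

via the locally competitive algorithm (LCA): membrane potentials ``u``
follow ``tau du/dt = -u + A^T s_e - W s`` with rates ``s = max(u - beta,
0)`` and lateral competition ``W = A^T A - I``.  After each presented
location, ``A`` is updated online by the Hebbian-like rule
``dA = eta * (s_e - A s) s^T`` with negative weights clipped to zero and
columns renormalized to unit length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .entorhinal import EntorhinalPopulation

__all__ = [
    "ModelConfig",
    "NetworkState",
    "InferenceResult",
    "init_network",
    "lca_infer",
    "lca_infer_batch",
    "learning_step",
    "sparse_cost",
    "fit_dictionary",
    "train",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the sparse coding network.

    Defaults are the standard training settings: membrane time constant
    tau = 10 ms, threshold beta = 0.3, 200 Euler steps of 0.8 ms per
    presentation, learning rate eta = 0.03 over 20,000 epochs, and 100
    hippocampal cells.
    """

    tau_ms: float = 10.0
    beta: float = 0.3
    dt_ms: float = 0.8
    n_steps: int = 200
    eta: float = 0.03
    n_epochs: int = 20000
    n_hippocampal: int = 100
    noise_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_ms <= 0 or self.dt_ms <= 0:
            raise ValueError("tau_ms and dt_ms must be positive")
        if self.dt_ms / self.tau_ms >= 2:
            raise ValueError(
                f"dt/tau = {self.dt_ms / self.tau_ms:.3g} >= 2: forward Euler "
                "integration of the leak term would be unstable"
            )
        if self.beta < 0 or self.eta <= 0 or self.noise_amp < 0:
            raise ValueError("beta/noise_amp must be >= 0 and eta > 0")
        if self.n_steps < 1 or self.n_epochs < 0 or self.n_hippocampal < 1:
            raise ValueError("n_steps, n_epochs and n_hippocampal must be valid counts")

    @property
    def alpha(self) -> float:
        """Euler step ratio dt / tau."""
        return self.dt_ms / self.tau_ms


@dataclass
class NetworkState:
    """Dictionary ``A`` (n_entorhinal x n_hippocampal) and recurrence ``W``."""

    A: np.ndarray
    W: np.ndarray
    training_log: Optional[pd.DataFrame] = None
    n_dead_respawns: int = 0

    @property
    def n_entorhinal(self) -> int:
        return self.A.shape[0]

    @property
    def n_hippocampal(self) -> int:
        return self.A.shape[1]

    def recompute_w(self) -> None:
        self.W = self.A.T @ self.A - np.eye(self.n_hippocampal)

    def copy(self) -> "NetworkState":
        return NetworkState(
            A=self.A.copy(),
            W=self.W.copy(),
            training_log=self.training_log,
            n_dead_respawns=self.n_dead_respawns,
        )


@dataclass(frozen=True)
class InferenceResult:
    """Converged rates ``s_h`` and membrane potentials ``u_h`` for one input."""

    s_h: np.ndarray
    u_h: np.ndarray


def init_network(
    n_entorhinal: int, n_hippocampal: int, rng: np.random.Generator
) -> NetworkState:
    """Random non-negative dictionary with unit-length columns."""
    if n_entorhinal < 1 or n_hippocampal < 1:
        raise ValueError("layer sizes must be >= 1")
    A = rng.random((n_entorhinal, n_hippocampal))
    A /= np.linalg.norm(A, axis=0)
    state = NetworkState(A=A, W=np.empty((n_hippocampal, n_hippocampal)))
    state.recompute_w()
    return state


def lca_infer(
    state: NetworkState, s_e: np.ndarray, cfg: ModelConfig
) -> InferenceResult:
    """Run the thresholded competitive dynamics for a single input.

    Potentials start at zero and are integrated for exactly
    ``cfg.n_steps`` first-order Euler steps; no convergence test is
    applied.  Raises ``FloatingPointError`` if the integration diverges.
    """
    s_e = np.asarray(s_e, dtype=float)
    if s_e.shape != (state.n_entorhinal,):
        raise ValueError(
            f"s_e must have shape ({state.n_entorhinal},), got {s_e.shape}"
        )
    b = state.A.T @ s_e
    s, u, status = _kernels.lca_loop(
        b, state.W, cfg.beta, cfg.alpha, cfg.n_steps
    )
    if status or not np.all(np.isfinite(u)):
        raise FloatingPointError(
            "LCA integration diverged (|u| exceeded guard); check dt/tau and inputs"
        )
    return InferenceResult(s_h=s, u_h=u)


def lca_infer_batch(
    state: NetworkState, S_e: np.ndarray, cfg: ModelConfig
) -> np.ndarray:
    """Vectorized inference: one row of rates per row of inputs."""
    S_e = np.atleast_2d(np.asarray(S_e, dtype=float))
    B = S_e @ state.A  # (m, n_h) feedforward drive
    U = np.zeros_like(B)
    alpha, beta = cfg.alpha, cfg.beta
    W = state.W
    for _ in range(cfg.n_steps):
        S = np.maximum(U - beta, 0.0)
        U += alpha * (B - U - S @ W)  # W is symmetric
    if not np.all(np.isfinite(U)):
        raise FloatingPointError("batch LCA integration diverged")
    return np.maximum(U - beta, 0.0)


def learning_step(
    state: NetworkState,
    s_e: np.ndarray,
    s_h: np.ndarray,
    eta: float,
    rng: Optional[np.random.Generator] = None,
) -> NetworkState:
    """Apply one online dictionary update in place.

    ``A <- A + eta (s_e - A s_h) s_h^T`` restricted to the active columns
    (the update is zero elsewhere), negative entries clipped, touched
    columns renormalized to unit length and the corresponding rows/columns
    of ``W = A^T A - I`` refreshed.  A column whose norm collapses to zero
    is re-randomized (requires ``rng``); the event is logged.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    A, W = state.A, state.W
    s_h = np.asarray(s_h, dtype=float)
    active = np.flatnonzero(s_h > 0)
    if active.size == 0:
        return state
    resid = s_e - A[:, active] @ s_h[active]
    A[:, active] = np.maximum(
        A[:, active] + eta * np.outer(resid, s_h[active]), 0.0
    )
    norms = np.linalg.norm(A[:, active], axis=0)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        if rng is None:
            rng = np.random.default_rng()
        logger.warning("re-randomizing %d dead dictionary column(s)", dead.size)
        state.n_dead_respawns += dead.size
        for d in dead:
            col = rng.random(A.shape[0])
            A[:, active[d]] = col
            norms[d] = np.linalg.norm(col)
    A[:, active] /= norms
    G = A.T @ A[:, active]
    W[:, active] = G
    W[active, :] = G.T
    W[active, active] -= 1.0
    return state


def sparse_cost(
    state: NetworkState, s_e: np.ndarray, s_h: np.ndarray, beta: float
) -> float:
    """Sparse coding objective: 1/2 ||s_e - A s_h||^2 + beta * sum(s_h)."""
    resid = np.asarray(s_e, dtype=float) - state.A @ np.asarray(s_h, dtype=float)
    return float(0.5 * resid @ resid + beta * np.sum(s_h))


def fit_dictionary(
    E: np.ndarray,
    cfg: ModelConfig,
    rng: np.random.Generator,
    location_sequence: Optional[Sequence[int]] = None,
    log_every: int = 100,
    chunk_size: int = 2000,
) -> NetworkState:
    """Train the dictionary on rows of ``E`` (one row per location).

    Each epoch presents one location: uniformly random by default, or the
    next entry of ``location_sequence`` (cycled if shorter than
    ``cfg.n_epochs``).  The returned state carries a training log
    (epoch, cost, active_fraction) sampled every ``log_every`` epochs.
    """
    E = np.ascontiguousarray(E, dtype=float)
    n_loc, n_e = E.shape
    state = init_network(n_e, cfg.n_hippocampal, rng)
    if location_sequence is not None:
        location_sequence = np.asarray(location_sequence, dtype=np.int64)
        if location_sequence.size == 0:
            raise ValueError("location_sequence is empty")
        if location_sequence.min() < 0 or location_sequence.max() >= n_loc:
            raise ValueError("location_sequence indices out of range")
    use_noise = cfg.noise_amp > 0
    log_rows = []
    pos = 0
    while pos < cfg.n_epochs:
        m = min(chunk_size, cfg.n_epochs - pos)
        if location_sequence is None:
            locs = rng.integers(0, n_loc, size=m, dtype=np.int64)
        else:
            locs = location_sequence[
                (pos + np.arange(m)) % location_sequence.size
            ]
        if use_noise:
            noise = cfg.noise_amp * rng.standard_normal((m, n_e))
        else:
            noise = np.zeros((1, 1))
        respawn = rng.random((4, n_e))
        cost_log = np.empty(m)
        act_log = np.empty(m)
        status, n_dead = _kernels.train_chunk(
            E,
            state.A,
            state.W,
            np.ascontiguousarray(locs),
            noise,
            use_noise,
            cfg.beta,
            cfg.alpha,
            cfg.n_steps,
            cfg.eta,
            respawn,
            cost_log,
            act_log,
        )
        if status:
            raise FloatingPointError(
                f"training diverged around epoch {pos}; check dt/tau, eta and inputs"
            )
        if n_dead:
            logger.warning("re-randomized %d dead column(s) in chunk at %d", n_dead, pos)
            state.n_dead_respawns += n_dead
        sel = np.flatnonzero((pos + np.arange(m)) % log_every == 0)
        for i in sel:
            log_rows.append((pos + i, cost_log[i], act_log[i]))
        pos += m
    state.training_log = pd.DataFrame(
        log_rows, columns=["epoch", "cost", "active_fraction"]
    )
    return state


def train(
    pop: EntorhinalPopulation,
    cfg: ModelConfig,
    rng: np.random.Generator,
    location_source: Optional[Sequence[int]] = None,
    log_every: int = 100,
) -> NetworkState:
    """Train the network on an entorhinal population.

    ``location_source`` may be None (uniformly random locations) or a
    sequence of location indices such as a discretized running trajectory.
    """
    return fit_dictionary(
        pop.E, cfg, rng, location_sequence=location_source, log_every=log_every
    )
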