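"""Shared fixtures.

The expensive end-to-end runs (full training at published settings) are
session-scoped and shared between the acceptance tests; small fixtures for
unit tests train reduced networks in a few seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

import placemap as pm

REPLICATE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def env():
    return pm.make_environment()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_grid_pop(env):
    """81 mathematical grid cells (3 spacings, 3 orientations, 3x3 phases)."""
    return pm.make_math_grid_population(env, 3, 3, 3, 3)


@pytest.fixture(scope="session")
def small_trained(small_grid_pop):
    """A reduced trained network for analysis tests (seconds, not minutes)."""
    cfg = pm.ModelConfig(n_hippocampal=30, n_epochs=5000)
    state = pm.train(small_grid_pop, cfg, np.random.default_rng(7))
    return state, small_grid_pop, cfg


def _replicates(preset, seeds=REPLICATE_SEEDS, **overrides):
    return [
        pm.run_experiment(pm.get_preset(preset, **overrides), seed=s) for s in seeds
    ]


@pytest.fixture(scope="session")
def fig3_runs():
    """Diverse mathematical grids, published settings, 3 replicate seeds."""
    return _replicates("fig3")


@pytest.fixture(scope="session")
def fig8_runs():
    """Realistic module-sampled grids, 3 replicate seeds."""
    return _replicates("fig8")


@pytest.fixture(scope="session")
def fig9_runs():
    """Two smallest grid modules only, 3 replicate seeds."""
    return _replicates("fig9")


@pytest.fixture(scope="session")
def fig10_runs():
    """Largest-spacing module, 20 hippocampal cells, 3 replicate seeds."""
    return _replicates("fig10")


@pytest.fixture(scope="session")
def fig11_runs():
    """Weakly spatial inputs (eta = 0.01, 30k epochs), 3 replicate seeds."""
    return _replicates("fig11")


@pytest.fixture(scope="session")
def nh_sweep():
    """Place-map resolution sweep over hippocampal population sizes."""
    return pm.run_nh_sweep(n_values=(30, 40, 50, 60, 80, 100), base="fig3", seed=1)
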