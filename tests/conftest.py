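"""Shared fixtures. Expensive circuit-model runs are session-scoped so the
behavioral, dopamine and stimulation analyses all reuse them."""

from __future__ import annotations

import numpy as np
import pytest

from creditseq.plasticity_model import PlasticityParams, run_plasticity_session
from creditseq.task_engine import TaskConfig


@pytest.fixture(scope="session")
def pl_run():
    """5000-trial pl_like plasticity run with the printed model parameters."""
    rng = np.random.default_rng(1)
    return run_plasticity_session("pl_like", TaskConfig(), PlasticityParams(), 5000, rng)


@pytest.fixture(scope="session")
def early_run():
    """5000-trial early-only control (alpha=0.003, beta_value=1000)."""
    rng = np.random.default_rng(1)
    params = PlasticityParams(alpha=0.003, beta_value=1000.0)
    return run_plasticity_session("early_only", TaskConfig(), params, 5000, rng)


@pytest.fixture(scope="session")
def mth_run():
    """3000-trial mTH-like run (weak, inconsistent sequences)."""
    rng = np.random.default_rng(1)
    return run_plasticity_session("mth_like", TaskConfig(), PlasticityParams(), 3000, rng)


@pytest.fixture(scope="session")
def stim_run():
    """3000-trial pl_like run with stimulation on 10% of trials."""
    rng = np.random.default_rng(2)
    return run_plasticity_session(
        "pl_like", TaskConfig(), PlasticityParams(), 3000, rng, stim_fraction_of_trials=0.1
    )


@pytest.fixture(scope="session")
def desk_agent():
    """Scaled-down trained dynamics agent (shared by the network tests).

    32 units and 15-trial episodes train reliably within the 10^4-episode
    budget; the seed instantiates one such agent.
    """
    from creditseq.dynamics_model import DynamicsConfig, train_dynamics_model

    rng = np.random.default_rng(1)
    cfg = DynamicsConfig.desk(n_units=32, trials_per_episode=15)
    agent, curve = train_dynamics_model(cfg, rng)
    return agent, curve
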