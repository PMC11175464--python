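import numpy as np
import pytest

from creditassign import (ModelParams, TaskConfig, generate_session,
                          get_model, simulate)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    return TaskConfig(n_blocks=2, n_trials_per_block=25, seed=77)


@pytest.fixture(scope="session")
def simulated_agent(small_config):
    """One surprise-minimization agent on a small session."""
    rng = np.random.default_rng(42)
    spec = get_model("surprise_min")
    params = ModelParams(alpha=0.4, beta=5.0, rho=0.5, epsilon=0.5)
    blocks = generate_session(small_config, rng)
    trials, trace = simulate(spec, params, blocks, rng)
    return {"spec": spec, "params": params, "blocks": blocks,
            "trials": trials, "trace": trace}


@pytest.fixture(scope="session")
def convergence_sims():
    """The 1000-run Monte-Carlo validation cohort (3 x 100 trials,
    prior-drawn parameters); shared by the simulation-statistics tests."""
    from creditassign.validate import run_convergence_sims
    rng = np.random.default_rng(2024)
    return run_convergence_sims(1000, rng=rng)
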