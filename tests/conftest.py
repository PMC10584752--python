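import numpy as np
import pytest

import sdtkernels as sk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def vanilla_disc_table():
    """A moderate vanilla discrimination campaign reused across tests."""
    return sk.simulate_campaign(
        sk.AgentConfig(), "discrimination", n_agents=30, n_trials=60, seed=101
    )


@pytest.fixture(scope="session")
def vanilla_det_table():
    return sk.simulate_campaign(
        sk.AgentConfig(), "detection", n_agents=30, n_trials=60, seed=102
    )


@pytest.fixture(scope="session")
def heuristic_table():
    """Synthetic luminance sessions from a weighted-heuristic observer."""
    observer = sk.ObserverSpec(
        kind="weighted_heuristic",
        w_pos=1.5,
        w_neg=-0.75,
        w_sum=0.0,
        decision_noise_sd=0.3,
        confidence_noise_sd=0.05,
    )
    design = sk.ExperimentDesign(
        n_subjects=30, trials_per_task=56, boost_fraction=0.5, seed=103
    )
    return sk.run_synthetic_experiment(sk.StimulusSpec(), observer, design)
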