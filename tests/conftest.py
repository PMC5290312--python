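import numpy as np
import pytest

from circinfer import (
    DesignConfig,
    ModelParams,
    SimulatedParticipant,
    generate_design,
    simulate_responses,
)


@pytest.fixture(scope="session")
def default_design():
    """One seeded default-task design (240 trials)."""
    return generate_design(DesignConfig(seed=123))


@pytest.fixture(scope="session")
def noisy_circular_participant(default_design):
    """A circular responder with identifiable parameters and motor noise."""
    params = ModelParams.circular(w_s=0.9, w_p=0.75, alpha_s=1.8, alpha_p=0.6)
    responder = SimulatedParticipant(true_params=params, response_noise_sd=0.05, seed=42)
    return params, simulate_responses(default_design, responder)


@pytest.fixture(scope="session")
def logit_grid():
    """Dense grid of (L_s, L_p) pairs covering the task's logit range."""
    ls = np.linspace(-2.2, 2.2, 23)
    lp = np.linspace(-2.2, 2.2, 23)
    LS, LP = np.meshgrid(ls, lp)
    return LS.ravel(), LP.ravel()
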