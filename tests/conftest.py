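"""Shared fixtures: small synthetic sessions generated at test time."""

import numpy as np
import pytest

from oromotor.simulate import SimConfig, generate_session


@pytest.fixture(scope="session")
def feeding_session():
    """A control feeding session (~1000 direction windows, all octants)."""
    return generate_session(SimConfig(n_trials=10, trial_dur=10.0, seed=7))


@pytest.fixture(scope="session")
def drinking_session():
    """A compact control drinking session, 9 trials (3 per spout)."""
    return generate_session(
        SimConfig(behavior="drinking", n_trials=9, trial_dur=6.0, seed=8))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
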