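import numpy as np
import pytest
from hypothesis import settings

import spikefield as sf

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_model():
    """Magnitude-coded population small enough for fast decoding tests."""
    return sf.generate_population(
        n_neurons=300,
        sheet_size=(3.0, 3.0),
        n_channels=8,
        units_per_channel=2,
        pooling_radius=1.5,
        baseline_rate=10.0,
        suppression_s0=0.4,
        suppression_tau=24.0,
        memorability_gain=0.3,
        channel_noise_sd=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sessions(small_model):
    sessions = []
    for i in range(2):
        trials = sf.generate_task_sequence(
            60, (1, 2, 4, 8, 16), seed=30 + i, session_id=f"sess{i}"
        )
        sessions.append(sf.simulate_responses(small_model, trials, seed=50 + i))
    return sessions


@pytest.fixture(scope="session")
def small_pseudo(small_sessions):
    return sf.build_pseudopopulation(
        small_sessions,
        band_responses=[s.hga_proxy for s in small_sessions],
        target_n_backs=(1, 2, 4, 8, 16),
    )


@pytest.fixture(scope="session")
def constant_memorability():
    """Sampler pinning memorability at 0.5 (unit gain)."""
    return lambda rng, n: np.full(n, 0.5)
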