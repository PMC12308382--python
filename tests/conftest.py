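"""Shared fixtures: synthetic corpora and small trained models.

Everything is generated programmatically and seeded; the heavier trained
models are session-scoped so the whole suite pays for each training once.
"""

import pytest

from fluorogen.fixtures import FixtureSpec, generate_molecules
from fluorogen.generator import BetaSchedule, TrainConfig, train_generator


@pytest.fixture(scope="session")
def toy_molecules():
    """20 distinct small fixture molecules."""
    return generate_molecules(FixtureSpec(n_molecules=20, max_tokens=8, seed=3))


@pytest.fixture(scope="session")
def corpus100():
    """100 distinct fixture molecules for codec-level checks."""
    return generate_molecules(FixtureSpec(n_molecules=100, max_tokens=10, seed=11))


@pytest.fixture(scope="session")
def overfit_ae(toy_molecules):
    """Reconstruction-only model (beta = 0) overfit on the 20-molecule set."""
    cfg = TrainConfig(
        schedule=BetaSchedule(kind="fixed", beta_start=0.0, beta_end=0.0),
        latent_dim=16, hidden_dim=128, epochs=400, batch_size=20,
        seed=0, lr=2e-3)
    return train_generator(toy_molecules, cfg)


@pytest.fixture(scope="session")
def small_model(corpus100):
    """Adaptive-schedule model on 100 molecules; cheap but structured."""
    cfg = TrainConfig(
        schedule=BetaSchedule(kind="exponential", beta_start=1.0,
                              beta_end=0.01, rho=0.95),
        latent_dim=16, hidden_dim=128, epochs=120, batch_size=32,
        seed=0, lr=2e-3)
    return train_generator(corpus100, cfg)
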