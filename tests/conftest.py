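"""Shared synthetic fixtures: a small crystal target, simulated amplitudes
and the analyzed target context, generated once per session."""

import numpy as np
import pytest

from mrllg import prep, synth
from mrllg.config import RunConfig


@pytest.fixture(scope="session")
def target60():
    """60-residue P1 toy crystal structure."""
    return synth.make_target(60, n_copies=1, space_group="P1", seed=0)


@pytest.fixture(scope="session")
def refl60(target60):
    """Noise-free amplitudes of the 60-residue target, complete to 2.5 A."""
    return synth.simulate_amplitudes(target60, d_min=2.5, noise_frac=0.0, seed=0)


@pytest.fixture(scope="session")
def refl60_noisy(target60):
    """Amplitudes with 3% multiplicative noise."""
    return synth.simulate_amplitudes(target60, d_min=2.5, noise_frac=0.03, seed=0)


@pytest.fixture(scope="session")
def context60(target60):
    return prep.analyze_target(target60)


@pytest.fixture(scope="session")
def chain60(target60):
    return target60.chain_model("A")


@pytest.fixture()
def fast_config():
    """Scoring configuration without the rigid-body stage (predictions
    generated in the target frame are already in register)."""
    return RunConfig(rigid_body=False, compute_gdt=False)


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same stream regardless of
    # execution order or subset selection
    return np.random.default_rng(1234)
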