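import numpy as np
import pytest

from gluecoop.synthetic import (
    ScenarioSpec,
    ToyComplexSpec,
    make_toy_ternary_system,
    random_binding_scenario,
    sample_ensemble,
)


@pytest.fixture(scope="session")
def seed7_scenario():
    """Closure-exact random scenario: (rates, constants, totals)."""
    return random_binding_scenario(ScenarioSpec(seed=7))


@pytest.fixture(scope="session")
def seed11_scenario():
    return random_binding_scenario(ScenarioSpec(seed=11))


@pytest.fixture(scope="session")
def toy_complex():
    """Toy bead complex (seed 3, planted A-L salt bridge) + ground truth."""
    return make_toy_ternary_system(ToyComplexSpec(seed=3, salt_bridge="AL"))


@pytest.fixture(scope="session")
def noisy_ensemble(toy_complex):
    cx, _ = toy_complex
    return sample_ensemble(cx, n_frames=20, sigma=0.1, seed=13)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
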