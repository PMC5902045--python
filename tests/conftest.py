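import numpy as np
import pytest

from motifstrat import PWM, SyntheticSpec, random_ground_truth_pwm


@pytest.fixture
def sharp_pwm():
    """Width-4 motif strongly preferring ACGT."""
    probs = np.full((4, 4), 0.01)
    np.fill_diagonal(probs, 0.97)
    return PWM(probs, name="sharp")


@pytest.fixture
def soft_pwm():
    """Width-2 motif with graded preferences."""
    return PWM(
        np.array([[0.7, 0.1, 0.1, 0.1], [0.25, 0.25, 0.25, 0.25]]),
        name="soft",
    )


@pytest.fixture(scope="session")
def truth_pwm():
    """Ground-truth motif of the synthetic study: width 10, ~12 bits."""
    return random_ground_truth_pwm(10, 12.0, seed=11)


@pytest.fixture(scope="session")
def study_spec(truth_pwm):
    return SyntheticSpec(ground_truth=truth_pwm, seed=11, mu_sel=6.0)


def random_pwm(rng, width):
    g = rng.gamma(0.8, size=(width, 4)) + 1e-6
    return PWM(g / g.sum(axis=1, keepdims=True), name="rand")
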