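import numpy as np
import pytest

from metamotif.pwm import PWM, log_odds_matrix
from metamotif.simulate import simulate_pwm_library


@pytest.fixture(scope="session")
def pwm_library():
    """Small deterministic PWM library (first matrix near-consensus)."""
    pwms = simulate_pwm_library(5, length_range=(8, 12), seed=7, matrices_per_tf=2)
    for p in pwms:
        log_odds_matrix(p)
    return pwms


@pytest.fixture()
def sharp_pwm():
    """Length-6 nearly deterministic matrix (consensus ACGTAC)."""
    counts = np.full((6, 4), 1.0)
    for i, b in enumerate("ACGTAC"):
        counts[i, "ACGT".index(b)] = 97.0
    return log_odds_matrix(PWM(matrix_id="SHARP", tf_names=["SHARP_TF"], counts=counts))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
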