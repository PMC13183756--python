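import numpy as np
import pytest

from vocalib.confusion import ConfusionProfile, recall_biased_profile


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def identity_profile():
    """A essentially perfect classifier: lambda = I with negligible noise."""
    return ConfusionProfile(mu=np.eye(4), alpha=np.full((4, 4), 1e6), tau=1e4)


@pytest.fixture(scope="session")
def vtc_like_profile():
    return recall_biased_profile()


@pytest.fixture(scope="session")
def adversarial_profile():
    """Strong CHI<->FEM confusion plus sibling-relevant OCH->adult leakage."""
    mu = np.array(
        [
            [0.65, 0.08, 0.25, 0.02],
            [0.10, 0.50, 0.20, 0.10],
            [0.25, 0.05, 0.65, 0.08],
            [0.02, 0.03, 0.10, 0.55],
        ]
    )
    return ConfusionProfile(mu=mu, alpha=np.full((4, 4), 6.0), tau=0.7)
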