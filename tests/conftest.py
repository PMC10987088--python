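import pytest

from signalogic.dataprep import normalize_pipeline
from signalogic.synthetic import demo_model_pair, make_truth, simulate_dataset


@pytest.fixture(scope="session")
def demo_pair():
    """Fixed sensitive/resistant logic-model pair with its regulator table."""
    return demo_model_pair()


@pytest.fixture(scope="session")
def small_truth():
    """Deterministic 12-node ground truth with the 16-condition design."""
    return make_truth(n_nodes=12, seed=1)


@pytest.fixture(scope="session")
def noisefree_dataset(small_truth):
    raw = simulate_dataset(small_truth, noise_sd=0.0, low_bead_rate=0.0, seed=3)
    return normalize_pipeline(raw, small_truth.design)
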