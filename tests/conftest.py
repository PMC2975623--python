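import numpy as np
import pytest

from rareweight.cohort import VariantPanel
from rareweight.evaluation import ExperimentConfig, _attempt_sample, _replicate_rng


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_panel():
    """Six-site panel: four rare (two causative), two common."""
    panel = VariantPanel(freqs=np.array([0.001, 0.004, 0.0005, 0.008, 0.1, 0.3]))
    panel.causative = np.array([True, False, True, False, True, True])
    return panel


@pytest.fixture(scope="session")
def simulated_sample():
    """One full-chain extreme-phenotype case/control sample at baseline."""
    cfg = ExperimentConfig()
    sample = _attempt_sample(cfg, _replicate_rng(991, 0, 0))
    assert sample is not None
    return sample
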