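import numpy as np
import pytest

import nirsbci as nb


@pytest.fixture(scope="session")
def small_dataset():
    """Four simulated subjects, 8 trials per class, default effect size."""
    cfg = nb.SimulationConfig(n_subjects=4, trials_per_class=8, rng_seed=7)
    recs, truths, manifest = nb.simulate_dataset(cfg)
    return cfg, recs, truths, manifest


@pytest.fixture(scope="session")
def small_epochs(small_dataset):
    _, recs, _, _ = small_dataset
    return nb.epochs_from_recordings(recs)


@pytest.fixture(scope="session")
def strong_epochs():
    """Three subjects with a response amplitude far above the noise floor."""
    cfg = nb.SimulationConfig(n_subjects=3, trials_per_class=10,
                              effect_amplitude=0.05, rng_seed=2)
    recs, _, _ = nb.simulate_dataset(cfg)
    return nb.epochs_from_recordings(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
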