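import numpy as np
import pytest

import wmdrift as wd


@pytest.fixture(scope="session")
def small_dataset():
    """One participant, 160 trials, 8 channels: the workhorse fixture.

    Small enough to generate in well under a second, large enough for the
    stratified 8-fold machinery over 16 orientation bins.
    """
    cfg = wd.SynthConfig(n_participants=1, n_trials=160, n_channels=8, seed=42)
    epochs, table, truth = wd.generate_dataset(cfg)
    return cfg, epochs, table, truth


@pytest.fixture(scope="session")
def small_features(small_dataset):
    _, epochs, _, _ = small_dataset
    return {ev: wd.featurize(epochs[ev]) for ev in wd.EVENTS}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
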