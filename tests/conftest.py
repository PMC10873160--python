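import numpy as np
import pytest

import delaypinn as dp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unimodal_scenario():
    return dp.preset_scenarios(n_traces=12)["unimodal"]


@pytest.fixture(scope="session")
def small_dataset(unimodal_scenario):
    tts, truth = dp.generate_dataset(unimodal_scenario, seed=7)
    return tts, truth


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    """One quick shared fit, reused by inference/CLI-level tests."""
    tts, _ = small_dataset
    config = dp.TrainingConfig(max_epochs=400, patience=400,
                               collocation_count=41)
    model, history = dp.train(tts, model_config=dp.ModelConfig(smax=2.0),
                              config=config, seed=3)
    return model, history, tts
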