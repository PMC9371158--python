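import numpy as np
import pytest

import wearcam as w
from wearcam.synthgen import SynthConfig


@pytest.fixture(scope="session")
def small_cohort() -> w.Dataset:
    """A small full-vocabulary cohort: 6 subjects x 17 activities x 3 windows."""
    cfg = SynthConfig(
        n_subjects=6,
        windows_per_subject_activity=3,
        signature_strength=0.6,
        noise_sd=0.4,
    )
    return w.generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def tiny_trained_model(small_cohort):
    """A quickly trained small HAR model plus its SD plan (shared, read-only)."""
    plan = w.split_subject_dependent(small_cohort, 0.3, 42)
    spec = w.build_small_architecture(len(small_cohort.activity_vocabulary), n_filters=8)
    config = w.TrainConfig(epochs=4, batch_size=64, seed=0)
    model = w.train_model(spec, small_cohort, plan, config)
    return model, plan


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
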