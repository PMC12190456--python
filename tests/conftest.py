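import numpy as np
import pytest

from complexion.labels import LABELS
from complexion.synthetic import SyntheticConfig, canonical_landmarks, generate_dataset, generate_samples


@pytest.fixture(scope="session")
def template_landmarks():
    """Jitter-free canonical landmark set on a 256-px frame."""
    return canonical_landmarks(256, jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        class_counts={lab.value: 8 for lab in LABELS}, seed=5, landmark_jitter_sd=1.0
    )


@pytest.fixture(scope="session")
def small_records(small_config):
    """40 rendered samples (8 per class), in memory."""
    return generate_samples(small_config)


@pytest.fixture(scope="session")
def small_samples(small_records):
    return [r.sample for r in small_records]


@pytest.fixture(scope="session")
def small_dataset_dir(tmp_path_factory, small_config):
    """The same 40 samples written to disk with manifest and sidecars."""
    out = tmp_path_factory.mktemp("synth40")
    generate_dataset(small_config, out)
    return out


@pytest.fixture(scope="session")
def recovery_samples():
    """310 well-separated samples (62 per class) for recovery experiments."""
    cfg = SyntheticConfig(class_counts={lab.value: 62 for lab in LABELS}, seed=7)
    samples = [r.sample for r in generate_samples(cfg)]
    order = np.random.default_rng(0).permutation(len(samples))
    train = [samples[i] for i in order[:250]]
    test = [samples[i] for i in order[250:310]]
    return train, test
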