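import numpy as np
import pytest

from mirloop.features import feature_frame
from mirloop.folding import fold_fallback
from mirloop.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_benchmark():
    """60+60 synthetic records with fallback structures and features.

    Small enough to featurize once per session; used by ensemble and
    evaluation tests that need a learnable binary task.
    """
    config = SynthConfig(n_pos=60, n_neg=60, seed=42)
    records, manifest = generate_dataset(config)
    structures = [fold_fallback(r.sequence) for r in records]
    features = feature_frame(records, structures)
    return records, manifest, features


@pytest.fixture(scope="session")
def small_Xy(small_benchmark):
    _, manifest, features = small_benchmark
    return features.values, manifest["label"].values


@pytest.fixture
def rng():
    return np.random.default_rng(7)
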