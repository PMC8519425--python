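import numpy as np
import pytest

from virtustain.synthetic_data import SceneSpec, generate_dataset, split_by_well


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def scene_dataset():
    """20 default scenes over 4 wells, used by training and pipeline tests."""
    examples, manifest = generate_dataset(20, SceneSpec(seed=42), wells=4)
    return examples, manifest


@pytest.fixture(scope="session")
def splits(scene_dataset):
    examples, _ = scene_dataset
    return split_by_well(examples, 2, 1)
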