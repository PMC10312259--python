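import pytest

from sgmine import ErdosRenyiSpec, preset_dataset, sample_er_dataset


@pytest.fixture
def toy_dataset():
    """Handcrafted 3-node, 10-vs-10 dataset with known testability structure."""
    return preset_dataset("toy-fig4-style")


@pytest.fixture
def small_er_dataset():
    spec = ErdosRenyiSpec(3, 0.3)
    return sample_er_dataset(spec, spec, 8, 8, seed=123)
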