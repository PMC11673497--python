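import numpy as np
import pytest

from medsr import DegradationSpec, ModelConfig, PhantomSpec, build_model, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest sensible architecture; fast to run on any input."""
    return ModelConfig(
        scale=2, feature_width=8, num_blocks=1, esa_reduction=4,
        head_width=4, head_width2=4, seed=7,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return build_model(tiny_config)


@pytest.fixture(scope="session")
def small_dataset():
    """Ten 128px CT/MRI-like phantoms, clean bicubic 2x degradation."""
    return make_dataset(
        10,
        PhantomSpec(modality="ct_mri_like", size=128, seed=3),
        DegradationSpec(scale=2, seed=30_000),
    )
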