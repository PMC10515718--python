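import numpy as np
import pytest

from dme_deeplab import (
    AsppConfig,
    DecoderConfig,
    ModelConfig,
    PhantomSpec,
    generate_dataset,
)


def compact_model_config(mode: str = "sawtooth_cascade",
                         rates: tuple[int, ...] = (1, 3, 9, 1, 3, 9),
                         seed: int = 0) -> ModelConfig:
    """Width-reduced model used throughout the tests: same topology as the
    default, ~330k parameters, fast enough for CPU training."""
    return ModelConfig(
        width_mult=0.25,
        aspp=AsppConfig(mode=mode, rates=rates, branch_channels=64),
        decoder=DecoderConfig(low_level_reduced_channels=16, refine_channels=64),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """16/2/2 split of 64x64 phantoms for smoke training."""
    root = tmp_path_factory.mktemp("phantoms64")
    spec = PhantomSpec(height=64, width=64, n_lesions=2,
                       lesion_radius_range=(2.0, 7.0), seed=0)
    manifest = generate_dataset(spec, 16, 2, 2, seed=7, out_dir=root)
    return root, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
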