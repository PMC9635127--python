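import numpy as np
import pytest

from pssmformer import (
    GeneratorConfig,
    LabeledDataset,
    ModelConfig,
    PSSMProfile,
    generate_dataset,
    init_weights,
)


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def default_weights(default_config):
    return init_weights(default_config, np.random.default_rng(12345))


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """A quick-to-train cohort: 30 adaptors vs 270 others, short profiles."""
    return generate_dataset(
        GeneratorConfig(n_pos=30, n_neg=270, min_len=18, max_len=120, seed=11)
    )


def random_profile(rng: np.random.Generator, length: int, label=None) -> PSSMProfile:
    from pssmformer import RESIDUE_ORDER

    residues = "".join(RESIDUE_ORDER[i] for i in rng.integers(0, 20, size=length))
    scores = rng.integers(-10, 11, size=(length, 20)).astype(float)
    return PSSMProfile(id=f"p{rng.integers(1e9)}", residues=residues,
                       scores=scores, label=label)
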