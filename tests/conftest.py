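import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# SVC(probability=True) deprecation chatter from sklearn 1.9
warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)


@pytest.fixture(scope="session")
def small_dataset():
    """60 motif-planted fragments with a strong signal."""
    from kacestack.simulate import (MotifSpec, SyntheticDatasetSpec,
                                    generate_dataset)

    return generate_dataset(
        SyntheticDatasetSpec(30, 30, MotifSpec(p_signal=0.9), seed=7)
    )


@pytest.fixture(scope="session")
def small_hybrid(small_dataset):
    from kacestack.encoders import encode_hybrid

    return encode_hybrid(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
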