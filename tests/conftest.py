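import numpy as np
import pytest

from spindlelat.preprocess import EpochMask

FS = 256.0


@pytest.fixture
def fs():
    return FS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def clean_mask(n_epochs: int, stage: str = "N2") -> EpochMask:
    """All-included artifact-free mask of `n_epochs` 30-s epochs."""
    return EpochMask(
        included=np.ones(n_epochs, dtype=bool),
        stages=[stage] * n_epochs,
        epoch_length=30.0,
        artifact_subintervals=[[] for _ in range(n_epochs)],
    )


@pytest.fixture
def nrem_mask_10():
    return clean_mask(10)
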