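import numpy as np
import pytest

from tandemhmm.model import ModelParams


@pytest.fixture(scope="session")
def tiny_params() -> ModelParams:
    """A small, fully explicit model: k=4, one consecutive indel each way."""
    return ModelParams(k=4, max_insert=1, max_delete=1,
                       indel_open=0.02, nu_in=0.02, nu_out=0.03)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
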