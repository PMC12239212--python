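import pytest

from evorescue.params import ModelParams, preset


@pytest.fixture(scope="session")
def melanoma() -> ModelParams:
    return preset("melanoma_a375")


@pytest.fixture(scope="session")
def scaled() -> ModelParams:
    """Melanoma rates at a desk-runnable operating point.

    The mutation rate is raised to 1e-3 and the tumor shrunk to 1,000
    cells so that N/N* stays of order one while a replicate takes ~1e4
    events instead of ~1e8.
    """
    return preset("melanoma_a375").with_(n_init=1000, v=1e-3)
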