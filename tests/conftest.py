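import pytest

from dermadiff import preset, simulate


@pytest.fixture(scope="session")
def base_run():
    """Base-case finite-reservoir transient, 240 h, shared across tests."""
    return simulate(preset("base_case"))


@pytest.fixture(scope="session")
def infinite_run():
    return simulate(preset("infinite"))


@pytest.fixture(scope="session")
def removal_run():
    return simulate(preset("removal_72h"))
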