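import pytest

from htnsim import default_parameters, fixture_parameters


@pytest.fixture(scope="session")
def params():
    """The packaged default parameter set (immutable; session-shared)."""
    return default_parameters()


@pytest.fixture(scope="session")
def tiny():
    """The 2-cohort closed-form fixture set."""
    return fixture_parameters("tiny")
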