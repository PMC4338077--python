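import pytest

from quorumsignal import GameParams, enumerate_strategies


@pytest.fixture(scope="session")
def full_space():
    return enumerate_strategies(reduced=False)


@pytest.fixture(scope="session")
def reduced_space():
    return enumerate_strategies(reduced=True)


@pytest.fixture(scope="session")
def default_params():
    """Headline parameter point: Z=100, N=9, M=5, c=0.5, c_S=0.2, F=10,
    lambda=0.5, gamma=5, defector shirkers."""
    return GameParams()


@pytest.fixture(scope="session")
def cycling_params():
    """Parameter point with no robust strategy and an invasion loop:
    Z=100, N=9, M=5, c=0.3, c_S=0.06, gamma=0.5, F=10, lambda=0.8."""
    return GameParams(Z=100, N=9, M=5, c=0.3, c_S=0.06, F=10.0, lam=0.8, gamma=0.5)
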