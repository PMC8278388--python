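import pytest

from pepal.judred import JudredCalculator
from pepal.oracle import SyntheticOracleConfig


@pytest.fixture(scope="session")
def calc():
    return JudredCalculator()


@pytest.fixture(scope="session")
def oracle_config():
    return SyntheticOracleConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticOracleConfig(noise_slope=0.0)
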