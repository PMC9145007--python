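import pytest

from retrochannel.synthetic import fixture_suite


@pytest.fixture(scope="session")
def fixtures():
    return fixture_suite()


@pytest.fixture(scope="session")
def unit_rates(fixtures):
    return fixtures["siso_unit_rates"].rates
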