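import pytest

from txcost import paper_fixture


@pytest.fixture(scope="session")
def study():
    """The bundled study inputs (strategy, dialysis arm, currency rate)."""
    return paper_fixture()


@pytest.fixture(scope="session")
def strategy(study):
    return study.strategy


@pytest.fixture(scope="session")
def rate(study):
    return study.rate


@pytest.fixture(scope="session")
def dialysis(study):
    return study.dialysis


@pytest.fixture(scope="session")
def events_by_name(strategy):
    return {ae.name: ae for ae in strategy.adverse_events}
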