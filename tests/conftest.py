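import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from raptorcount import CountRecord, load_protocol

# make_record is a pure factory handing out fresh ids, so sharing it across
# generated examples is safe
settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol():
    return load_protocol()


@pytest.fixture(scope="session")
def hierarchy(protocol):
    return protocol[0]


@pytest.fixture(scope="session")
def config(protocol):
    return protocol[1]


@pytest.fixture
def make_record():
    """Factory for valid records with sensible defaults."""
    counter = iter(range(1, 100_000))

    def _make(**kw):
        base = dict(
            id=next(counter),
            date=dt.date(2015, 9, 1),
            time=dt.time(10, 0, 0),
            species="HB",
            number=1,
            station=1,
            location="E1",
        )
        base.update(kw)
        return CountRecord(**base)

    return _make
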