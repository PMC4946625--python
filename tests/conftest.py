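import pytest

from netincon.partitions import Design, DesignSet, enumerate_designs


@pytest.fixture(scope="session")
def full_t4() -> DesignSet:
    return enumerate_designs("ABCD")


@pytest.fixture(scope="session")
def triangle() -> DesignSet:
    return DesignSet([Design("AB"), Design("AC"), Design("BC")])


@pytest.fixture(scope="session")
def star_plus_loop() -> DesignSet:
    return DesignSet([Design("AB"), Design("AC"), Design("AD"), Design("BC")])


def designs(*labels: str) -> DesignSet:
    return DesignSet([Design.parse(s) for s in labels])
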