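import pytest

from codonmap import (
    GLOBAL_OPTIMAL_MAP,
    ORIGINAL_MAP,
    load_genetic_code,
    load_genetic_codes,
)


@pytest.fixture(scope="session")
def all_codes():
    return load_genetic_codes()


@pytest.fixture(scope="session")
def code1():
    return load_genetic_code(1)


@pytest.fixture(scope="session")
def code2():
    return load_genetic_code(2)


@pytest.fixture(scope="session")
def original_map():
    """The previously published map T=0, C=1, A=2, G=3."""
    return ORIGINAL_MAP


@pytest.fixture(scope="session")
def global_map():
    """The rank-sum global optimum A=1, C=0, G=3, T=2."""
    return GLOBAL_OPTIMAL_MAP
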