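import pytest

import poolforge as pf


@pytest.fixture(scope="session")
def gb1_pool():
    return pf.build_gb1()


@pytest.fixture(scope="session")
def mpra_pool():
    return pf.build_mpra()


@pytest.fixture(scope="session")
def splice_pool():
    return pf.build_splice()
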