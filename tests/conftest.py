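import pytest

from neotcr.simulate import builtin_germline, default_clone_pairs


@pytest.fixture(scope="session")
def germline():
    return builtin_germline()


@pytest.fixture(scope="session")
def clone_pairs():
    return default_clone_pairs()
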