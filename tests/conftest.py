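import pytest

from permamp import datasets


@pytest.fixture(scope="session")
def parent():
    return datasets.w5k_parent()


@pytest.fixture(scope="session")
def library():
    return datasets.w5k_library()


@pytest.fixture(scope="session")
def mic_panel():
    return datasets.w5k_mic_panel()


@pytest.fixture(scope="session")
def hc10_table():
    return datasets.w5k_hc10()
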