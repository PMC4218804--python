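import pytest

from valveflux.synthetic import core_model, toy_class, toy_linear, toy_parallel, toy_shortlong


@pytest.fixture
def lin():
    return toy_linear()


@pytest.fixture
def par():
    return toy_parallel()


@pytest.fixture
def shortlong():
    return toy_shortlong()


@pytest.fixture
def classify():
    return toy_class()


@pytest.fixture
def core():
    return core_model()
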