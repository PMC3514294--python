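import pytest

from itmflow import ModelQuery, make_fixture


@pytest.fixture
def path3():
    """Undirected unit-weight chain a-b-c: every model has a closed form here."""
    return make_fixture("path", 3)


@pytest.fixture
def absorbing_query():
    return ModelQuery("absorbing", sinks=("c",))


@pytest.fixture
def emitting_query():
    return ModelQuery("emitting", sources=("a",))


@pytest.fixture
def channel_query():
    return ModelQuery("channel", sources=("a",), sinks=("c",))
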