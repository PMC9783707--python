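import pytest

from pipscore import demo_kb


@pytest.fixture(scope="session")
def demo():
    """The bundled demonstration knowledge base and its prevalence table."""
    return demo_kb()


@pytest.fixture(scope="session")
def kb(demo):
    return demo[0]


@pytest.fixture(scope="session")
def prev(demo):
    return demo[1]
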