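import pytest

from netcanvas.core import build_network, build_tree


@pytest.fixture
def triangle_network():
    return build_network([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def triangle_layout():
    return {"A": (0.0, 0.0), "B": (2.0, 0.0), "C": (1.0, 1.5)}


@pytest.fixture
def caterpillar_tree():
    # ((A,B),C) with unit branch lengths
    return build_tree({"A": "i", "B": "i", "i": "r", "C": "r"})


@pytest.fixture
def fresh_registry():
    from netcanvas.ingestion import ProviderRegistry

    return ProviderRegistry()
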