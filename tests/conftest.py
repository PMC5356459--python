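import pytest

from taxcompat import build, fig1_profile


@pytest.fixture
def fig1():
    return fig1_profile()


@pytest.fixture
def t1(fig1):
    return fig1.trees[0]


@pytest.fixture
def t2(fig1):
    return fig1.trees[1]


@pytest.fixture
def t3(fig1):
    return fig1.trees[2]


@pytest.fixture
def chain_abc():
    return build(("a", [("b", ["c"])]))
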