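import pytest

from neural_automata import Alphabet, Encoding
from neural_automata.demo import demo_encodings, demo_initial_state, demo_machine


@pytest.fixture(scope="session")
def abc():
    return Alphabet(("a", "b", "c"), "a")


@pytest.fixture(scope="session")
def demo_vs():
    return demo_machine()


@pytest.fixture(scope="session")
def demo_encs():
    return demo_encodings()


@pytest.fixture(scope="session")
def demo_s0():
    return demo_initial_state()


@pytest.fixture(scope="session")
def canonical3():
    return Encoding.canonical(3)
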