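import pytest

from jellyswim import Environment, load_animal


@pytest.fixture(scope="session")
def animal1():
    """Larger field animal: d_r 11.3 cm, t_c 0.70 s, t_r 0.73 s."""
    return load_animal("animal1")


@pytest.fixture(scope="session")
def animal2():
    """Smaller field animal: d_r 9.8 cm, t_c 0.87 s, t_r 0.90 s."""
    return load_animal("animal2")


@pytest.fixture(scope="session")
def env():
    return Environment()
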