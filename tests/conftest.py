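import numpy as np
import pytest

from olisim import (
    ancestor_sequence,
    extend_by_self_priming,
    extended_amplicon,
    primer_sequences,
)


@pytest.fixture(scope="session")
def ancestor() -> str:
    return ancestor_sequence()


@pytest.fixture(scope="session")
def extended(ancestor) -> str:
    return extend_by_self_priming(ancestor)


@pytest.fixture(scope="session")
def amplicon() -> str:
    return extended_amplicon()


@pytest.fixture(scope="session")
def primers() -> tuple[str, str]:
    return primer_sequences()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20130904)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
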