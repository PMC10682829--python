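import random

import numpy as np
import pytest

from fmo_roadmap import load_reference_panel
from fmo_roadmap.core_io import AA20


@pytest.fixture(scope="session")
def panel():
    """The deterministic synthetic fixture panel (seed 0)."""
    return load_reference_panel("fixture")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_residues(rng, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture()
def make_random_residues(rng):
    return lambda length: random_residues(rng, length)
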