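import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from editcode import fold as fe
from editcode import synth as sy


@pytest.fixture(scope="session")
def model():
    return fe.DEFAULT_MODEL


@pytest.fixture(scope="session")
def tiny_spec():
    # 17 nt: small enough for brute-force verification (n <= 22)
    return sy.SynthSpec(
        seed=0, ext5=1, ext3=1, stem1=3, stem2=2, loop5=1, loop3=1, hairpin=3,
        n_singles=10, n_doubles=4,
    )


@pytest.fixture(scope="session")
def tiny_substrate(tiny_spec):
    return sy.gen_substrate(tiny_spec)


@pytest.fixture(scope="session")
def small_spec():
    return sy.SynthSpec(seed=0, n_singles=30, n_doubles=10)


@pytest.fixture(scope="session")
def small_substrate(small_spec):
    return sy.gen_substrate(small_spec)


@pytest.fixture(scope="session")
def small_library(small_substrate, small_spec):
    lib = sy.gen_library(small_substrate, small_spec)
    lib, truth = sy.plant_editing(lib, small_substrate, small_spec)
    return lib


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
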