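import logging

import numpy as np
import pytest

from cestfit import (
    PoolSpec,
    PoolTable,
    make_phantom1,
    make_phantom2,
    pool_table_phantom1,
    pool_table_phantom2,
)

logging.getLogger("cestfit").setLevel(logging.ERROR)

#: Ground-truth (amplitude, frequency, width) per region and pool, phantom 1.
PHANTOM1_TRUTH = {
    "left": {
        "water": (0.95, 0.0, 0.5),
        "amide": (0.30, 3.5, 0.5),
        "creatine": (0.10, 1.9, 0.5),
        "oh": (0.03, 1.0, 0.5),
        "mt": (0.03, -2.0, 15.0),
    },
    "right": {
        "water": (0.95, 0.0, 0.5),
        "amide": (0.10, 3.5, 0.5),
        "creatine": (0.30, 1.9, 0.5),
        "oh": (0.03, 1.0, 0.5),
        "mt": (0.03, -2.0, 15.0),
    },
    "outer": {
        "water": (0.95, 0.0, 0.5),
    },
}

#: Ground truth per region for phantom 2 (AF / NP differ in GAG only).
PHANTOM2_TRUTH = {
    "af": {
        "water": (0.75, 0.0, 2.0),
        "gag": (0.03, 1.0, 1.0),
        "noe_2.6": (0.05, -2.6, 1.0),
        "noe_1.0": (0.001, -1.0, 2.0),
        "nh": (0.03, 3.2, 0.5),
        "mt": (0.15, -2.4, 10.0),
    },
    "np": {
        "water": (0.75, 0.0, 2.0),
        "gag": (0.06, 1.0, 1.0),
        "noe_2.6": (0.05, -2.6, 1.0),
        "noe_1.0": (0.001, -1.0, 2.0),
        "nh": (0.03, 3.2, 0.5),
        "mt": (0.15, -2.4, 10.0),
    },
}


@pytest.fixture(scope="session")
def phantom1_small():
    """Phantom 1 at 32x32, noiseless."""
    return make_phantom1((32, 32))


@pytest.fixture(scope="session")
def phantom2_small():
    """Phantom 2 at 64x64, noiseless."""
    return make_phantom2((64, 64))


@pytest.fixture(scope="session")
def table1():
    return pool_table_phantom1()


@pytest.fixture(scope="session")
def table2():
    return pool_table_phantom2()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_pools(rng, k):
    """Random pool parameter array (K, 3) with well-separated scales."""
    a = rng.uniform(0.01, 0.9, k)
    w = rng.uniform(-5.0, 5.0, k)
    s = rng.uniform(0.3, 10.0, k)
    return np.column_stack([a, w, s])


def single_pool_table(a=0.3, w=3.5, s=0.5):
    return PoolTable([
        PoolSpec("pool", a, 0.0, 1.0, w, w - 1.0, w + 1.0, s, 0.05, 5.0)
    ])
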