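import numpy as np
import pytest

from ntcana.synthetic import (
    DEMO_TORSIONS,
    SETTABLE_TORSIONS,
    make_demo_class_table,
)

DEMO_SEED = 7


@pytest.fixture(scope="session")
def demo():
    """Demo class table plus its sampled golden set (seeded)."""
    return make_demo_class_table(seed=DEMO_SEED)


@pytest.fixture(scope="session")
def demo_table(demo):
    return demo[0]


@pytest.fixture(scope="session")
def demo_golden(demo):
    return demo[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def aa_torsions():
    """The A-form demo torsion set as a name->value dict."""
    return dict(zip(SETTABLE_TORSIONS, DEMO_TORSIONS["AA00"][1]))


def random_torsions(rng, n=1):
    """Random settable-torsion dicts, uniform on [0, 360)."""
    out = [
        dict(zip(SETTABLE_TORSIONS, rng.uniform(0.0, 360.0, len(SETTABLE_TORSIONS))))
        for _ in range(n)
    ]
    return out[0] if n == 1 else out
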