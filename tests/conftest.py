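import numpy as np
import pytest

from axonzip.statics import ZipperGeometry, ZipperMechanics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def wide_zipper():
    """Asymmetric zipper with a comfortable interior equilibrium."""
    geom = ZipperGeometry(A=(-10.0, 10.0), B=(10.0, 10.0), C=(0.0, -40.0),
                          V=(0.0, 0.0))
    mech = ZipperMechanics(T1=1.0, T2=1.5, S=0.2)
    return geom, mech


def random_valid_config(rng, n=1):
    """Random non-degenerate zipper configurations for property checks."""
    out = []
    for _ in range(n):
        A = rng.uniform(-20, 20, 2) + np.array([-15.0, 15.0])
        B = rng.uniform(-20, 20, 2) + np.array([15.0, 15.0])
        C = rng.uniform(-20, 20, 2) + np.array([0.0, -40.0])
        V = rng.uniform(-5, 5, 2)
        T1, T2 = rng.uniform(0.5, 3.0, 2)
        S = rng.uniform(0.05, 0.8)
        out.append((ZipperGeometry(A, B, C, V), ZipperMechanics(T1, T2, S)))
    return out
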