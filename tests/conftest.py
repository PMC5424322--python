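import numpy as np
import pytest

from cvmkit import CVMParams, simulate

ALL_KIND_PARAMS = {
    "ucvm": CVMParams("ucvm", tau=5.0, eta=3.0),
    "acvm": CVMParams("acvm", tau=5.0, eta=3.0, mu=(2.0, 0.0)),
    "rcvm": CVMParams("rcvm", tau=5.0, eta=3.0, omega=2.0),
    "racvm": CVMParams("racvm", tau=5.0, eta=3.0, mu=(2.0, 0.0), omega=2.0),
}


@pytest.fixture(scope="session")
def quartet_params():
    return ALL_KIND_PARAMS


@pytest.fixture(scope="session")
def dense_racvm_track():
    """High-resolution rotational-advective track (500 steps at dt=0.01)."""
    return simulate(ALL_KIND_PARAMS["racvm"], n=500, dt=0.01, seed=1234)


@pytest.fixture(scope="session")
def dense_ucvm_track():
    return simulate(ALL_KIND_PARAMS["ucvm"], n=500, dt=0.01, seed=4321)


def random_params(rng, kind=None):
    """A random valid parameter set, for property-style sweeps."""
    kind = kind or rng.choice(["ucvm", "acvm", "rcvm", "racvm"])
    return CVMParams(
        kind,
        tau=float(10 ** rng.uniform(-0.7, 1.2)),
        eta=float(10 ** rng.uniform(-0.5, 0.8)),
        mu=tuple(rng.normal(0, 2, 2)) if kind in ("acvm", "racvm") else (0.0, 0.0),
        omega=float(rng.uniform(-3, 3)) if kind in ("rcvm", "racvm") else 0.0,
    )
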