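import numpy as np
import pandas as pd
import pytest

from kinmotif import build_nfblb_model
from kinmotif.fixtures import FixtureSpec, PlantedEffect, generate_fixture


@pytest.fixture(scope="session")
def nfblb():
    return build_nfblb_model()


@pytest.fixture(scope="session")
def unit_params(nfblb):
    """All catalytic and Michaelis constants equal to one."""
    return np.ones(nfblb.n_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240115)


@pytest.fixture()
def planted_fixture():
    """Synthetic screened matrix with a strong class-1 bias on K_BA and
    score shifts that make K_BA's motif precision-associated."""
    spec = FixtureSpec(
        M=74,
        N=20_000,
        effects={
            "K_BA": PlantedEffect(class_index=1, planting_fraction=0.85,
                                  precision_shift=0.5),
        },
        seed=11,
    )
    return generate_fixture(spec)
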