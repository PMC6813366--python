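import numpy as np
import pytest

from rrpool import (
    CohortSpec,
    MembraneModel,
    NoiseParams,
    ParamDistributions,
    StimulusProtocol,
)


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture(scope="session")
def membrane() -> MembraneModel:
    return MembraneModel()


@pytest.fixture(scope="session")
def quiet_noise() -> NoiseParams:
    """Effectively noiseless OU parameters (sigma far below quantal size)."""
    return NoiseParams(sigma_mv=1e-9, tau_ms=28.2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def make_spec(**kwargs) -> CohortSpec:
    defaults = dict(
        lam=0.0,
        n_connections=10,
        n_sweeps=20,
        distributions=ParamDistributions(gmax_ns=3.2),
    )
    defaults.update(kwargs)
    return CohortSpec(**defaults)
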