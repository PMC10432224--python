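import numpy as np
import pytest

from chemosense.geometry import ReceptorConfig
from chemosense.homogenized import HomogenizedParams, kappa_from_receptors
from chemosense.kmc import SimulationConfig, simulate

# reference study conditions: source at R=5, N=201 receptors covering 5%
# of the membrane, D=1 (cell radius = 1)


@pytest.fixture(scope="session")
def receptors() -> ReceptorConfig:
    return ReceptorConfig.fibonacci(201, 0.05)


@pytest.fixture(scope="session")
def ref_params(receptors) -> HomogenizedParams:
    kap = kappa_from_receptors(receptors.sigma, receptors.a, 1.0)
    return HomogenizedParams(R=5.0, D=1.0, kappa=kap)


@pytest.fixture(scope="session")
def reference_events(receptors):
    """One medium simulation reused by several distributional tests."""
    cfg = SimulationConfig(M=10_000, R=5.0, D=1.0, receptors=receptors, seed=1234)
    return simulate(cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20230615)
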