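import numpy as np
import pytest

from ctpspoly import ThermoParams, default_params


@pytest.fixture(scope="session")
def defaults() -> ThermoParams:
    """The shipped calibrated parameter set (fast; loaded from the package)."""
    return default_params()


@pytest.fixture()
def simple_params() -> ThermoParams:
    """A hand-sized polymerizing parameter set for unit checks."""
    return ThermoParams(K_uf=100.0, K_cf=50.0, K_cp=10.0, K_e=1.0,
                        E_nuc=2.0, k_max=5.0)


@pytest.fixture()
def isodesmic_params() -> ThermoParams:
    """No nucleation barrier, unit elongation constant (bare ladder)."""
    return ThermoParams(K_uf=100.0, K_cf=50.0, K_cp=10.0, K_e=1.0,
                        E_nuc=0.0, k_max=5.0)


def truncated_sums(z: float, K_e: float, sigma: float, n_max: int = 10**6):
    """Brute-force polymer mass and number by direct geometric summation."""
    n = np.arange(2, n_max + 1, dtype=float)
    w = K_e * sigma * z**n
    return float(np.sum(n * w)), float(np.sum(w))
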