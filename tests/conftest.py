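import numpy as np
import pytest

from pascar.calibration import FitSpec, SimOptions
from pascar.kinetics import BindingParams, KPParams, ResponseParams
from pascar.synthetic import TABLE_DEFAULTS


@pytest.fixture(scope="session")
def truth():
    """Reference calibrated parameter set used as synthetic ground truth."""
    return dict(TABLE_DEFAULTS)


@pytest.fixture(scope="session")
def binding_high():
    """High-affinity CAR (K_D 17.6 nM in copy-number units)."""
    return BindingParams(k_off=9.0e-5, K_D=2.39)


@pytest.fixture(scope="session")
def binding_low():
    """Low-affinity CAR (K_D 210 nM in copy-number units)."""
    return BindingParams(k_off=6.8e-4, K_D=28.47)


@pytest.fixture(scope="session")
def kp_ref():
    return KPParams(k_p=0.0072, N=7.0)


@pytest.fixture(scope="session")
def coarse_sim():
    """Fast discretisation used wherever a fit runs inside a test."""
    return SimOptions(n_bins_R=16, n_bins_H=14, n_steps=60)


@pytest.fixture(scope="session")
def free_kp_bounds():
    """Default free-parameter bounds for KP-variant fits."""
    return {
        "lambda_c": (1e-9, 1e-7),
        "rho_c": (1e-10, 1e-7),
        "k_p": (1e-3, 1e-1),
        "N": (1.0, 12.0),
        "mu_c": (6.0, 9.0),
        "sigma_R": (0.1, 1.2),
    }
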