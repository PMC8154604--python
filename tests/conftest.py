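import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from electrokin.constitutive import DielectricModel, InterfaceSpec, ViscosityModel

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dielectric():
    """Default dielectric model: decrement + saturation, multiplicative."""
    return DielectricModel()


@pytest.fixture(scope="session")
def viscosity():
    """Default viscosity model with the published fit coefficients."""
    return ViscosityModel()


@pytest.fixture(scope="session")
def constant_dielectric():
    """Dielectric model frozen at eps_w for every field and concentration."""
    return DielectricModel(eps_w=71.0, eps_ms=1.0, alpha=0.0, eps_n=71.0)


@pytest.fixture(scope="session")
def constant_viscosity():
    """Viscosity model frozen at eta_w."""
    return ViscosityModel(a_c1=0.0, a_c2=0.0, a_E1_par=0.0, a_E2_par=0.0,
                          a_E1_perp=0.0, a_E2_perp=0.0)


@pytest.fixture
def ideal_interface():
    """Interface with no steric, box or slip effects (Gouy-Chapman limit)."""
    def make(sigma0=0.1, c0=0.01):
        return InterfaceSpec(sigma0=sigma0, c0=c0, d=0.0, z_int=0.0, b_s=0.0)
    return make
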