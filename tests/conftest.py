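import numpy as np
import pytest

from phytohop.model import ModelParameters, load_parameters


@pytest.fixture(scope="session")
def params_a():
    return load_parameters("set-A")


@pytest.fixture(scope="session")
def params_b():
    return load_parameters("set-B")


@pytest.fixture(scope="session")
def toy_params():
    """Small symmetric model with analytically transparent structure."""
    return ModelParameters(E_vert=40.0, V6_S0=50.0, V6_S1=30.0, V5=5.0,
                           chi=0.0, theta6_CI=90.0, w0=1.0, sigma_w=10.0,
                           D_hb=4.0, a_hb=2.0, r0_hb=2.9, lambda_hb=1.0,
                           v_asym=10.0, gamma=1.0)


@pytest.fixture(scope="session")
def small_ensemble_a(params_a):
    """A modest packaged set-A ensemble shared by analysis unit tests."""
    from phytohop.photoanalysis import simulate_lifetime
    from phytohop.shdynamics import SHSettings

    fit, trajs = simulate_lifetime(params_a, 120, seed=11,
                                   settings=SHSettings(t_max_ps=12.0),
                                   n_boot=30)
    return fit, trajs
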