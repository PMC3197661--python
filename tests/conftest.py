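import numpy as np
import pytest

from dyadforage import ModelParameters, derive_parameters, solve_ess


@pytest.fixture(scope="session")
def toy_params():
    """Small deterministic game: point-mass cost 1, point-mass gain 2."""
    return ModelParameters(
        S=4, c_max=2, g_max=3,
        m_A=0.2, m_T=0.1, m_R=0.02,
        nu=2.0, mu_F=1.0, mu_R=1.0,
        psi=0.0, sigma_F=0.0, sigma_R=0.0,
    )


@pytest.fixture(scope="session")
def random_params_s20():
    """One random realistic parameter set at desk scale (S = 20)."""
    rng = np.random.default_rng(42)
    return derive_parameters(*rng.uniform(size=6), S=20)


@pytest.fixture(scope="session")
def solved_s20(random_params_s20):
    """A converged ESS at S = 20 with all interference costs zero."""
    return solve_ess(random_params_s20)
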