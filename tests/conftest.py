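import numpy as np
import pytest

from hdmtx.cohort import CohortConfig, simulate_cohort
from hdmtx.mapfit import PriorSpec
from hdmtx.pk import PKParameters, protocol_schedule


@pytest.fixture(scope="session")
def schedule():
    """The protocol 5 g/m^2 infusion."""
    return protocol_schedule(5000.0)


@pytest.fixture(scope="session")
def prior():
    return PriorSpec()


@pytest.fixture(scope="session")
def prior_mean_params():
    """The population initial estimates as a parameter set."""
    return PKParameters(V=9.03, ke=0.7, kcp=0.08, kpc=0.11)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient cohort shared across read-only tests."""
    return simulate_cohort(CohortConfig(n=60, seed=42))


def ode_concentration(params, schedule, t, rtol=1e-10):
    """Independent oracle: adaptive-step numeric integration of the
    two-compartment system."""
    from scipy.integrate import solve_ivp

    def rhs(u, A):
        rate = 0.0
        for start, end, r in schedule.segments:
            if start <= u < end:
                rate = r
        return [
            rate - (params.ke + params.kcp) * A[0] + params.kpc * A[1],
            params.kcp * A[0] - params.kpc * A[1],
        ]

    if t == 0:
        return 0.0
    sol = solve_ivp(rhs, (0.0, t), [0.0, 0.0], rtol=rtol, atol=1e-12, max_step=0.25)
    return sol.y[0, -1] / params.V


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
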