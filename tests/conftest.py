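import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adaptox import InitialCondition, ModelParams, Protocol, ProtocolSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    """Baseline parameterization (package defaults)."""
    return ModelParams()


@pytest.fixture(scope="session")
def init() -> InitialCondition:
    return InitialCondition()


@pytest.fixture(params=list(Protocol), ids=[p.value for p in Protocol])
def protocol(request) -> Protocol:
    return request.param


@pytest.fixture(scope="session")
def baseline_specs() -> dict[Protocol, ProtocolSpec]:
    return {p: ProtocolSpec(protocol=p) for p in Protocol}


#: published baseline TTPs (days) per protocol
PUBLISHED_BASELINE_TTPS = {
    Protocol.DAILY: 19.2,
    Protocol.ADAPTIVE: 44.0,
    Protocol.DAILY_TOX: 59.8,
    Protocol.ADAPTIVE_TOX: 79.1,
}


def rk4_reference(params, dose_schedule, t_end, dt=1e-4, init=None, failure=None):
    """Brute-force fixed-step reference integration of (S, R, C).

    Independent of the package's integrators: plain RK4 on the full
    right-hand side with drug impulses applied at the scheduled times.
    Returns (times, S, R, C) arrays, or the failure-crossing time if
    ``failure`` is given.
    """
    init = init or InitialCondition()
    S, R, C = init.S0, init.R0, init.C0
    doses = sorted(dose_schedule)
    n = int(round(t_end / dt))

    def f(S, R, C):
        dS = params.alpha_S * S * (1 - (S + R) / params.K) - params.delta * C * S
        dR = params.alpha_R * R * (1 - (params.beta * S + R) / params.K)
        dC = -params.lam * C
        return np.array([dS, dR, dC])

    out = [(0.0, S, R, C)]
    for i in range(n):
        t = i * dt
        while doses and doses[0] <= t + 1e-12:
            C += 1.0
            doses.pop(0)
        y = np.array([S, R, C])
        k1 = f(*y)
        k2 = f(*(y + dt / 2 * k1))
        k3 = f(*(y + dt / 2 * k2))
        k4 = f(*(y + dt * k3))
        S, R, C = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if failure is not None and S + R >= failure:
            prev = out[-1]
            frac = (failure - (prev[1] + prev[2])) / ((S + R) - (prev[1] + prev[2]))
            return t + frac * dt
        out.append((t + dt, S, R, C))
    if failure is not None:
        return None
    arr = np.array(out)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
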