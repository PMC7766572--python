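import numpy as np
import pytest

from cabinair import (
    BoxModelParams,
    NoiseModel,
    Scenario,
    generate_method2_session,
)

SECONDS_PER_HOUR = 3600.0


def integrate_box_model(t_h, params: BoxModelParams, max_step_h: float = 1e-4):
    """Independent oracle: brute-force numeric integration of
    dC/dt = K_gen - lambda * (C - CO2_0)."""
    from scipy.integrate import solve_ivp

    def rhs(_t, c):
        return params.generation_rate - params.air_exchange_rate * (c[0] - params.baseline)

    t_h = np.atleast_1d(np.asarray(t_h, dtype=float))
    sol = solve_ivp(
        rhs,
        (0.0, float(t_h[-1]) if t_h[-1] > 0 else 1e-12),
        [params.baseline + params.initial_offset],
        t_eval=t_h,
        max_step=max_step_h,
        rtol=1e-10,
        atol=1e-8,
    )
    return sol.y[0]


@pytest.fixture(scope="session")
def parked_session():
    """One noisy synthetic intermittent-RC session at 0 MPH, EE = 1620."""
    return generate_method2_session(
        ee_true=1620.0, speed=0.0, n_cycles=4, noise=NoiseModel(gaussian_sd=15.0, seed=42)
    )


@pytest.fixture
def default_scenario():
    """Single occupant, default simulation conditions (3.1 m^3, lambda = 1)."""
    return Scenario(air_exchange_rate=1.0, duration_h=0.5)
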