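"""Synthetic sensor traces, speed logs and ventilation sessions.

The study's raw drive recordings are emulated by running the forward
simulator and corrupting its output with a configurable sensor noise
model (additive Gaussian noise, optional linear drift, quantization to
the sensor's integer-ppm output).  Every generator is deterministic
given its parameters and seed, and returns a ground-truth record
sufficient to compute the expected output of any downstream pipeline
stage analytically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .calibration import DEFAULT_LAMBDA_SPEED_MODEL, LambdaSpeedModel, SpeedLog
from .model import (
    AmbientConditions,
    CabinSpec,
    OccupantProfile,
    ParameterError,
    SensorTrace,
)
from .simulate import ControllerPolicy, Scenario, SimulatedTrace, simulate

SECONDS_PER_HOUR = 3600.0

#: Nominal driving speeds tested in the underlying study [MPH].
STUDY_SPEEDS_MPH = (0.0, 16.0, 33.0, 49.0, 70.0)


@dataclass(frozen=True)
class NoiseModel:
    """Additive sensor imperfections applied to a simulated CO2 series.

    ``gaussian_sd`` [ppm] white noise, ``drift_rate`` [ppm/h] linear
    drift, and rounding to the nearest ``quantization`` step [ppm]
    (1 ppm matches integer sensor output; 0 disables rounding).
    """

    gaussian_sd: float = 15.0
    drift_rate: float = 0.0
    quantization: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0 or self.quantization < 0:
            raise ParameterError("noise magnitudes must be >= 0")

    def apply(self, timestamps: np.ndarray, co2: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        out = co2 + rng.normal(0.0, self.gaussian_sd, co2.shape) if self.gaussian_sd > 0 else co2.copy()
        if self.drift_rate != 0.0:
            out = out + self.drift_rate * (timestamps - timestamps[0]) / SECONDS_PER_HOUR
        if self.quantization > 0:
            out = np.round(out / self.quantization) * self.quantization
        return np.maximum(out, self.quantization if self.quantization > 0 else 1e-6)


def generate_trace(
    scenario: Scenario,
    noise: NoiseModel = NoiseModel(),
    temperature_c: float = 25.0,
    relative_humidity_pct: float = 40.0,
) -> tuple[SensorTrace, dict]:
    """Simulate a scenario and corrupt it into a sensor trace.

    Returns the noisy :class:`~cabinair.model.SensorTrace` and a
    ground-truth record bundling every generating parameter, the clean
    RC-on cycle boundaries, and the noise settings.
    """
    sim = simulate(scenario)
    co2 = noise.apply(sim.timestamps, sim.co2)
    n = sim.timestamps.size
    trace = SensorTrace(
        timestamps=sim.timestamps,
        co2=co2,
        temperature=np.full(n, temperature_c),
        relative_humidity=np.full(n, relative_humidity_pct),
    )
    truth = {
        "kgen_total": scenario.total_generation_rate(),
        "lambda_rc_on": scenario.resolved_lambda(),
        "baseline": scenario.ambient.baseline_co2,
        "initial_offset": scenario.initial_offset,
        "cabin_volume_m3": scenario.cabin.volume,
        "stpd_factor": scenario.stpd_factor,
        "occupants": [asdict(o) for o in scenario.occupants],
        "speed": scenario.speed,
        "duration_h": scenario.duration_h,
        "cycles": sim.cycles,
        "noise": asdict(noise),
    }
    if scenario.controller is not None:
        truth["controller"] = asdict(scenario.controller)
    return trace, truth


def generate_speed_log(
    nominal: float,
    duration_h: float,
    jitter_sd: float = 3.0,
    seed: int = 0,
    ar_coeff: float = 0.9,
) -> SpeedLog:
    """1 Hz speed log fluctuating around a nominal speed [MPH].

    Fluctuations follow a stationary first-order autoregressive process
    (coefficient ``ar_coeff``, marginal SD ``jitter_sd``), clipped at
    zero.  A nominal speed of 0 means the car is parked and the log is
    identically zero.
    """
    if nominal < 0:
        raise ParameterError("nominal speed must be >= 0")
    n = int(round(duration_h * SECONDS_PER_HOUR)) + 1
    t = np.arange(n, dtype=float)
    if nominal == 0.0 or jitter_sd == 0.0:
        return SpeedLog(t, np.full(n, nominal))
    rng = np.random.default_rng(seed)
    innov_sd = jitter_sd * np.sqrt(1.0 - ar_coeff**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, jitter_sd)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = ar_coeff * x[i - 1] + eps[i - 1]
    return SpeedLog(t, np.maximum(nominal + x, 0.0))


@dataclass
class Method2Session:
    """A complete synthetic intermittent-recirculation session."""

    trace: SensorTrace
    speed_log: SpeedLog
    #: RC-on (growth) intervals, (start_s, end_s)
    schedule: list[tuple[float, float]]
    truth: dict


def generate_method2_session(
    ee_true: float = 1620.0,
    speed: float = 0.0,
    n_cycles: int = 4,
    noise: NoiseModel = NoiseModel(),
    rq: float = 0.85,
    cabin: CabinSpec = CabinSpec(),
    ambient: AmbientConditions = AmbientConditions(baseline_co2=400.0),
    initial_offset: float = 50.0,
    policy: ControllerPolicy = ControllerPolicy(),
    lambda_model: LambdaSpeedModel = DEFAULT_LAMBDA_SPEED_MODEL,
    speed_jitter_sd: float = 3.0,
) -> Method2Session:
    """Controller-driven session with known driver energy expenditure.

    The cabin starts slightly above baseline (fresh-air level ~450 ppm),
    the controller purges at the trigger level, and exactly ``n_cycles``
    RC-on growth intervals are kept: the simulation runs long enough for
    all of them and the trace is truncated at the end of the ``n_cycles``-th
    purge.  The recorded schedule holds the true growth intervals; speed
    jitter is drawn independently of the CO2 noise.
    """
    if n_cycles < 1:
        raise ParameterError("need at least one cycle")
    # generous horizon: growth from near-baseline plus purge, per cycle
    horizon_h = max(1.0, n_cycles * 0.5)
    scenario = Scenario(
        occupants=[OccupantProfile(energy_expenditure=ee_true, respiratory_quotient=rq)],
        cabin=cabin,
        ambient=ambient,
        speed=speed,
        duration_h=horizon_h,
        controller=policy,
        lambda_model=lambda_model,
        initial_offset=initial_offset,
    )
    sim = simulate(scenario)
    if len(sim.cycles) < n_cycles:
        raise ParameterError(
            f"horizon too short: only {len(sim.cycles)} cycles completed"
        )
    schedule = [tuple(map(float, c)) for c in sim.cycles[:n_cycles]]
    purge_end = schedule[-1][1] + policy.purge_duration_min * 60.0
    keep = sim.timestamps <= min(purge_end, sim.timestamps[-1])
    clipped = SimulatedTrace(
        sim.timestamps[keep], sim.co2[keep], sim.rc_on[keep], schedule
    )
    co2 = noise.apply(clipped.timestamps, clipped.co2)
    n = clipped.timestamps.size
    trace = SensorTrace(clipped.timestamps, co2, np.full(n, 25.0), np.full(n, 40.0))
    duration_h = float(clipped.timestamps[-1]) / SECONDS_PER_HOUR
    speed_log = generate_speed_log(
        speed, duration_h, jitter_sd=speed_jitter_sd, seed=noise.seed + 1
    )
    truth = {
        "ee_true": ee_true,
        "rq": rq,
        "speed": speed,
        "kgen_total": scenario.total_generation_rate(),
        "lambda_rc_on": policy.lambda_rc_on
        if policy.lambda_rc_on is not None
        else scenario.resolved_lambda(),
        "baseline": ambient.baseline_co2,
        "initial_offset": initial_offset,
        "cabin_volume_m3": cabin.volume,
        "stpd_factor": scenario.stpd_factor,
        "n_cycles": n_cycles,
        "schedule": schedule,
        "controller": asdict(policy),
        "noise": asdict(noise),
    }
    return Method2Session(trace=trace, speed_log=speed_log, schedule=schedule, truth=truth)
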