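"""Forward scenario engine for cabin CO2 prediction.

Simulates the well-mixed box model for a configured cabin, occupant load
and ventilation state, either open-loop (constant air exchange rate) or
closed-loop under a recirculation (RC) controller that purges the cabin
whenever CO2 reaches a trigger level.  Within every interval of constant
(lambda, K_gen) the closed-form solution is applied exactly from the
interval's entry concentration, so the output matches a numeric ODE
integration to solver precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import DEFAULT_LAMBDA_SPEED_MODEL, LambdaSpeedModel
from .model import (
    AmbientConditions,
    BoxModelParams,
    CabinSpec,
    OccupantProfile,
    ParameterError,
    co2_profile,
    occupant_generation_rate,
    stpd_correction_factor,
)

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class ControllerPolicy:
    """Threshold-triggered recirculation controller.

    RC mode stays on (low exchange, CO2 builds up) until the concentration
    reaches ``trigger_high`` [ppm]; the controller then switches RC off for
    ``purge_duration_min`` minutes of fast exchange at ``lambda_rc_off``
    [1/h], and the cycle repeats.  ``lambda_rc_on`` of None means the
    scenario's own air exchange rate (explicit or speed-derived) applies
    while RC is on.
    """

    trigger_high: float = 1100.0
    purge_duration_min: float = 5.0
    lambda_rc_on: float | None = None
    lambda_rc_off: float = 22.0

    def __post_init__(self) -> None:
        if self.purge_duration_min <= 0:
            raise ParameterError("purge duration must be positive")
        if self.lambda_rc_on is not None and self.lambda_rc_off <= self.lambda_rc_on:
            raise ParameterError("purge lambda must exceed the RC-on lambda")


@dataclass
class Scenario:
    """A complete cabin-CO2 simulation setup.

    Exactly one of ``speed`` [MPH] or ``air_exchange_rate`` [1/h] must be
    set; a speed is mapped to lambda through ``lambda_model``.  Total CO2
    generation is the sum of the per-occupant rates (linear in occupancy).
    """

    occupants: list[OccupantProfile] = field(default_factory=lambda: [OccupantProfile()])
    cabin: CabinSpec = field(default_factory=CabinSpec)
    ambient: AmbientConditions = field(default_factory=AmbientConditions)
    speed: float | None = None
    air_exchange_rate: float | None = None
    duration_h: float = 1.0
    controller: ControllerPolicy | None = None
    time_step_s: float = 1.0
    lambda_model: LambdaSpeedModel = DEFAULT_LAMBDA_SPEED_MODEL
    initial_offset: float = 0.0

    def __post_init__(self) -> None:
        if (self.speed is None) == (self.air_exchange_rate is None):
            raise ParameterError("set exactly one of speed or air_exchange_rate")
        if self.speed is not None and self.speed < 0:
            raise ParameterError("speed must be >= 0")
        if self.air_exchange_rate is not None and self.air_exchange_rate < 0:
            raise ParameterError("air exchange rate must be >= 0")
        if self.duration_h <= 0:
            raise ParameterError("duration must be positive")
        if self.time_step_s <= 0:
            raise ParameterError("time step must be positive")
        if self.controller is not None and self.controller.trigger_high <= self.ambient.baseline_co2:
            raise ParameterError("controller trigger must exceed the ambient baseline")

    @property
    def stpd_factor(self) -> float:
        return stpd_correction_factor(self.ambient)

    def resolved_lambda(self) -> float:
        """Air exchange rate [1/h] while RC is on (explicit or speed-derived)."""
        if self.air_exchange_rate is not None:
            return float(self.air_exchange_rate)
        return float(self.lambda_model.predict(self.speed))

    def total_generation_rate(self) -> float:
        """Summed occupant K_gen [ppm/h]."""
        return sum(
            occupant_generation_rate(o, self.cabin, self.stpd_factor) for o in self.occupants
        )


@dataclass
class SimulatedTrace:
    """Simulator output: regular grid of time [s], CO2 [ppm] and RC state."""

    timestamps: np.ndarray
    co2: np.ndarray
    rc_on: np.ndarray
    #: (start_s, end_s) of each completed-or-truncated RC-on growth interval
    cycles: list[tuple[float, float]] = field(default_factory=list)


def simulate(scenario: Scenario) -> SimulatedTrace:
    """Run a scenario; dispatches to the controller loop when one is set."""
    if scenario.controller is not None:
        return simulate_controller(scenario)
    n = int(round(scenario.duration_h * SECONDS_PER_HOUR / scenario.time_step_s)) + 1
    t_s = np.arange(n) * scenario.time_step_s
    params = BoxModelParams(
        baseline=scenario.ambient.baseline_co2,
        initial_offset=scenario.initial_offset,
        generation_rate=scenario.total_generation_rate(),
        air_exchange_rate=scenario.resolved_lambda(),
    )
    co2 = co2_profile(t_s / SECONDS_PER_HOUR, params)
    return SimulatedTrace(
        t_s, np.atleast_1d(co2), np.ones(n, dtype=bool), [(float(t_s[0]), float(t_s[-1]))]
    )


def simulate_controller(scenario: Scenario) -> SimulatedTrace:
    """Closed-loop run under the scenario's :class:`ControllerPolicy`.

    Growth and purge intervals are each evaluated with the closed form from
    their entry concentration; the RC-off switch fires at the first sample
    at or above the trigger, so overshoot is bounded by one time step of
    growth.
    """
    policy = scenario.controller
    if policy is None:
        raise ParameterError("scenario has no controller policy")
    dt = scenario.time_step_s
    n = int(round(scenario.duration_h * SECONDS_PER_HOUR / dt)) + 1
    t_s = np.arange(n) * dt
    kgen = scenario.total_generation_rate()
    lam_on = policy.lambda_rc_on if policy.lambda_rc_on is not None else scenario.resolved_lambda()
    lam_off = policy.lambda_rc_off
    if lam_off <= lam_on:
        raise ParameterError("purge lambda must exceed the RC-on lambda")
    baseline = scenario.ambient.baseline_co2

    co2 = np.empty(n)
    rc_on = np.empty(n, dtype=bool)
    cycles: list[tuple[float, float]] = []

    i = 0
    conc = baseline + scenario.initial_offset
    on = True
    cycle_start = 0.0
    purge_steps = max(int(round(policy.purge_duration_min * 60.0 / dt)), 1)
    while i < n:
        lam = lam_on if on else lam_off
        params = BoxModelParams(baseline, conc - baseline, kgen, lam)
        rel_t = (t_s[i:] - t_s[i]) / SECONDS_PER_HOUR
        seg = np.atleast_1d(co2_profile(rel_t, params))
        if on:
            hits = np.nonzero(seg >= policy.trigger_high)[0]
            # switch at the first sample at/above trigger, but always
            # advance at least one step so a start above trigger terminates
            end = int(hits[0]) if hits.size and hits[0] > 0 else (int(hits[0]) + 1 if hits.size else seg.size - 1)
            end = min(end, seg.size - 1)
            stop = i + end
            co2[i : stop + 1] = seg[: end + 1]
            rc_on[i : stop + 1] = True
            if hits.size and stop < n - 1:
                cycles.append((cycle_start, float(t_s[stop])))
                on = False
            else:  # ran out of time (or never reaches trigger)
                cycles.append((cycle_start, float(t_s[min(stop, n - 1)])))
                break
        else:
            end = min(purge_steps, seg.size - 1)
            stop = i + end
            co2[i : stop + 1] = seg[: end + 1]
            rc_on[i : stop + 1] = False
            if stop >= n - 1:
                break
            on = True
            cycle_start = float(t_s[stop])
        conc = float(co2[stop])
        i = stop
    return SimulatedTrace(t_s, co2, rc_on, cycles)


def time_to_threshold(scenario: Scenario, threshold: float) -> float:
    """Minutes until an open-loop scenario first reaches ``threshold`` ppm.

    Closed-form inversion of the box model; returns ``math.inf`` when the
    steady-state concentration never reaches the threshold, and 0 when the
    starting concentration is already at or above it.
    """
    if scenario.controller is not None:
        raise ParameterError("threshold inversion requires an open-loop scenario")
    baseline = scenario.ambient.baseline_co2
    start = baseline + scenario.initial_offset
    if threshold <= start:
        return 0.0
    kgen = scenario.total_generation_rate()
    lam = scenario.resolved_lambda()
    if lam == 0.0:
        if kgen <= 0.0:
            return math.inf
        return (threshold - start) / kgen * 60.0
    steady = baseline + kgen / lam
    if steady <= threshold:
        return math.inf
    # baseline + (K/lam)(1-e^-lt) + offset e^-lt = threshold
    t_h = -math.log(
        (threshold - baseline - kgen / lam) / (scenario.initial_offset - kgen / lam)
    ) / lam
    return t_h * 60.0
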