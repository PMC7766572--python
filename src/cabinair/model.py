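"""Well-mixed cabin CO2 box model and indirect-calorimetry unit conversions.

The cabin is treated as a single well-mixed compartment exchanging air with
the outdoors at a first-order rate ``lambda`` [1/h] while occupants add CO2
at a constant rate ``K_gen`` [ppm/h]:

    dC/dt = K_gen - lambda * (C - C_ambient)

whose closed-form solution is :func:`co2_profile`.  The conversion chain
K_gen -> VCO2 (mL/min at standard temperature, pressure, dry — STPD) ->
energy expenditure (kcal/day, Weir equation) links the fitted generation
rate to the occupant's metabolic rate.

Units throughout: time in hours at this interface, concentration in ppm,
cabin volume in cubic metres, VCO2 in mL/min STPD, energy expenditure in
kcal/day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


# STPD reference conditions: 0 degC, 760 mmHg, dry air.
STANDARD_PRESSURE_MMHG = 760.0
ZERO_CELSIUS_KELVIN = 273.0

# Weir equation coefficients: EE [kcal/day] = 1.44 * (3.941 * VO2 + 1.11 * VCO2)
# with VO2 = VCO2 / RQ and gas rates in mL/min.
WEIR_DAY_FACTOR = 1.44
WEIR_O2_COEFF = 3.941
WEIR_CO2_COEFF = 1.11

#: Calibrated span of the CO2 sensing system [ppm]; readings above are
#: flagged (not rejected) as out of calibrated range.
CALIBRATED_CO2_MAX_PPM = 3000.0

ML_PER_M3 = 1.0e6


@dataclass(frozen=True)
class CabinSpec:
    """Vehicle cabin geometry.

    Parameters
    ----------
    volume : float
        Interior air volume [m^3].  Default 3.1 m^3, a mid-size sedan
        close to the median of the US light-duty fleet (110 ft^3).
    """

    volume: float = 3.1

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ParameterError(f"cabin volume must be positive, got {self.volume}")

    @property
    def volume_ml(self) -> float:
        return self.volume * ML_PER_M3


@dataclass(frozen=True)
class AmbientConditions:
    """Outdoor/ambient state used for the STPD correction and the baseline.

    The default is the STPD reference itself (760 mmHg, dry, 0 degC) so the
    correction factor is exactly 1 unless measured conditions are supplied.

    Parameters
    ----------
    barometric_pressure : float
        Station pressure [mmHg].
    water_vapor_pressure : float
        Partial pressure of water vapour [mmHg].
    temperature : float
        Air temperature [degC].
    baseline_co2 : float
        Outdoor CO2 concentration [ppm]; quality-controlled traces start
        near ~400 ppm.
    """

    barometric_pressure: float = STANDARD_PRESSURE_MMHG
    water_vapor_pressure: float = 0.0
    temperature: float = 0.0
    baseline_co2: float = 400.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.water_vapor_pressure < self.barometric_pressure):
            raise ParameterError(
                "water vapor pressure must satisfy 0 <= P_H2O < P_bar "
                f"(got {self.water_vapor_pressure} vs {self.barometric_pressure})"
            )
        if self.temperature <= -ZERO_CELSIUS_KELVIN:
            raise ParameterError(f"temperature below absolute zero: {self.temperature} degC")
        if not (300.0 <= self.baseline_co2 <= 600.0):
            raise ParameterError(
                f"baseline CO2 {self.baseline_co2} ppm outside plausible outdoor range [300, 600]"
            )


@dataclass(frozen=True)
class BoxModelParams:
    """Parameter tuple of the box-model solution.

    Parameters
    ----------
    baseline : float
        Ambient CO2 concentration CO2_0 [ppm].
    initial_offset : float
        Concentration above baseline at t = 0, CO2_i [ppm].
    generation_rate : float
        CO2 generation rate K_gen [ppm/h].
    air_exchange_rate : float
        First-order air exchange rate lambda [1/h].
    """

    baseline: float
    initial_offset: float
    generation_rate: float
    air_exchange_rate: float

    def __post_init__(self) -> None:
        if self.generation_rate < 0:
            raise ParameterError(f"generation rate must be >= 0, got {self.generation_rate}")
        if self.air_exchange_rate < 0:
            raise ParameterError(
                f"air exchange rate must be >= 0, got {self.air_exchange_rate}"
            )

    @property
    def steady_state(self) -> float:
        """Asymptotic concentration [ppm]; infinite when lambda = 0 and K_gen > 0."""
        if self.air_exchange_rate > 0:
            return self.baseline + self.generation_rate / self.air_exchange_rate
        return self.baseline + self.initial_offset if self.generation_rate == 0 else np.inf


@dataclass(frozen=True)
class OccupantProfile:
    """Metabolic description of one occupant.

    ``energy_expenditure`` [kcal/day] and ``respiratory_quotient`` are the
    stored quantities; the CO2 production rate ``vco2`` [mL/min STPD] is
    derived through the Weir relation so the three stay mutually consistent.
    """

    energy_expenditure: float = 1700.0
    respiratory_quotient: float = 0.85

    def __post_init__(self) -> None:
        if self.energy_expenditure < 0:
            raise ParameterError(
                f"energy expenditure must be >= 0, got {self.energy_expenditure}"
            )
        rq = self.respiratory_quotient
        if not (0.67 <= rq <= 1.3):
            raise ParameterError(
                f"respiratory quotient {rq} outside physiological range [0.67, 1.3]"
            )
        if not (0.7 <= rq <= 1.0):
            warnings.warn(
                f"respiratory quotient {rq} is outside the usual fuel-mixture "
                "range [0.7, 1.0]",
                stacklevel=2,
            )

    @property
    def vco2(self) -> float:
        """Volumetric CO2 production [mL/min STPD] implied by EE and RQ."""
        return ee_to_vco2(self.energy_expenditure, self.respiratory_quotient)


@dataclass
class SensorTrace:
    """A 1 Hz cabin sensor recording: CO2, temperature, relative humidity.

    Timestamps are seconds from trace start and must be strictly increasing.
    """

    timestamps: np.ndarray
    co2: np.ndarray
    temperature: np.ndarray = field(default=None)  # type: ignore[assignment]
    relative_humidity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        n = self.timestamps.size
        if self.temperature is None:
            self.temperature = np.full(n, 25.0)
        if self.relative_humidity is None:
            self.relative_humidity = np.full(n, 40.0)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.relative_humidity = np.asarray(self.relative_humidity, dtype=float)
        if not (self.co2.size == n and self.temperature.size == n and self.relative_humidity.size == n):
            raise ParameterError("trace columns have mismatched lengths")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise ParameterError(f"timestamps not strictly increasing at index {bad + 1}")
        if np.any(self.co2 <= 0):
            raise ParameterError("CO2 readings must be positive")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration_s(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) else 0.0

    @property
    def out_of_calibration(self) -> np.ndarray:
        """Boolean mask of readings above the calibrated sensor span."""
        return self.co2 > CALIBRATED_CO2_MAX_PPM

    def slice(self, start_s: float, end_s: float) -> "SensorTrace":
        """Samples with ``start_s <= t <= end_s``."""
        m = (self.timestamps >= start_s) & (self.timestamps <= end_s)
        return SensorTrace(
            self.timestamps[m], self.co2[m], self.temperature[m], self.relative_humidity[m]
        )


def co2_profile(t, params: BoxModelParams):
    """Closed-form cabin CO2 concentration at elapsed time ``t`` [h].

    Evaluates

        C(t) = CO2_0 + (K_gen / lambda) (1 - e^{-lambda t}) + CO2_i e^{-lambda t}

    with the analytic lambda -> 0 limit ``CO2_0 + K_gen t + CO2_i`` taken
    exactly at lambda = 0 (and reproduced to numerical continuity near it
    via ``expm1``).  ``t`` may be a scalar or array; returns ppm.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("elapsed time must be non-negative")
    lam = params.air_exchange_rate
    if lam == 0.0:
        growth = params.generation_rate * t
        decay = np.ones_like(t)
    else:
        # -expm1(-x)/lam is accurate down to lam ~ 0 (relative error O(eps)).
        decay = np.exp(-lam * t)
        growth = params.generation_rate * (-np.expm1(-lam * t)) / lam
    out = params.baseline + growth + params.initial_offset * decay
    return float(out) if out.ndim == 0 else out


def stpd_correction_factor(ambient: AmbientConditions) -> float:
    """Multiplicative ATP -> STPD gas-volume correction.

    CF = ((P_bar - P_H2O) / 760) * (273 / (T + 273)), dimensionless.
    """
    return (
        (ambient.barometric_pressure - ambient.water_vapor_pressure)
        / STANDARD_PRESSURE_MMHG
    ) * (ZERO_CELSIUS_KELVIN / (ambient.temperature + ZERO_CELSIUS_KELVIN))


def saturation_vapor_pressure(temperature_c: float) -> float:
    """Saturation water-vapour pressure [mmHg] via the Magnus approximation.

    Accurate to well under 1% against tabulated values over 0-50 degC.
    """
    hpa = 6.112 * np.exp(17.62 * temperature_c / (243.12 + temperature_c))
    return float(hpa * 0.750062)


def water_vapor_pressure_from_rh(temperature_c: float, relative_humidity_pct: float) -> float:
    """Ambient water-vapour partial pressure [mmHg] from RH [%] and T [degC]."""
    if not (0.0 <= relative_humidity_pct <= 100.0):
        raise ParameterError(f"relative humidity {relative_humidity_pct}% outside [0, 100]")
    return relative_humidity_pct / 100.0 * saturation_vapor_pressure(temperature_c)


def ambient_from_trace(
    trace: SensorTrace,
    barometric_pressure: float = STANDARD_PRESSURE_MMHG,
    baseline_co2: float = 400.0,
) -> AmbientConditions:
    """Ambient conditions for the STPD correction from a trace's mean T and RH."""
    t_mean = float(np.mean(trace.temperature))
    rh_mean = float(np.mean(trace.relative_humidity))
    return AmbientConditions(
        barometric_pressure=barometric_pressure,
        water_vapor_pressure=water_vapor_pressure_from_rh(t_mean, rh_mean),
        temperature=t_mean,
        baseline_co2=baseline_co2,
    )


def kgen_to_vco2(generation_rate: float, cabin: CabinSpec, cf: float = 1.0) -> float:
    """Convert a cabin generation rate [ppm/h] to occupant VCO2 [mL/min STPD].

    VCO2 = K_gen * 1e-6 * V_room[mL] * CF / 60.
    """
    if generation_rate < 0:
        raise ParameterError("generation rate must be >= 0")
    return generation_rate * 1e-6 * cabin.volume_ml * cf / 60.0


def vco2_to_kgen(vco2: float, cabin: CabinSpec, cf: float = 1.0) -> float:
    """Inverse of :func:`kgen_to_vco2`: VCO2 [mL/min] -> K_gen [ppm/h]."""
    if vco2 < 0:
        raise ParameterError("VCO2 must be >= 0")
    return vco2 * 60.0 / (1e-6 * cabin.volume_ml * cf)


def weir_coefficient(rq: float) -> float:
    """kcal/day produced per unit VCO2 [mL/min] at respiratory quotient ``rq``.

    1.44 * (3.941 / RQ + 1.11); approximately 8.275 at RQ = 0.85, the
    mixed-diet simplification commonly rounded to 8.273 in the indirect
    calorimetry literature.
    """
    if rq <= 0:
        raise ParameterError(f"respiratory quotient must be positive, got {rq}")
    return WEIR_DAY_FACTOR * (WEIR_O2_COEFF / rq + WEIR_CO2_COEFF)


def weir_ee(vco2: float, rq: float = 0.85) -> float:
    """Weir-equation energy expenditure [kcal/day] from VCO2 [mL/min STPD]."""
    if vco2 < 0:
        raise ParameterError("VCO2 must be >= 0")
    return weir_coefficient(rq) * vco2


def ee_to_vco2(ee: float, rq: float = 0.85) -> float:
    """Inverse Weir relation: EE [kcal/day] -> VCO2 [mL/min STPD]."""
    if ee < 0:
        raise ParameterError("energy expenditure must be >= 0")
    return ee / weir_coefficient(rq)


def occupant_generation_rate(
    occupant: OccupantProfile, cabin: CabinSpec, cf: float = 1.0
) -> float:
    """Cabin CO2 generation rate K_gen [ppm/h] one occupant produces."""
    return vco2_to_kgen(occupant.vco2, cabin, cf)
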