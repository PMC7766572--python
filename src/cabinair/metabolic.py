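"""Driver energy expenditure from intermittent-recirculation CO2 cycles.

Under the intermittent protocol the recirculation (RC) mode is left on
until cabin CO2 reaches ~1000-1100 ppm, then switched off for a few
minutes of fast purge; each RC-on interval is a "growth cycle".  This
module segments a sensor trace into growth cycles, fits the box model to
each cycle with the air exchange rate fixed from the lambda(speed) model
(only K_gen and the initial offset are estimated — a linear problem), and
converts the per-cycle generation rates to VCO2 and Weir-equation energy
expenditure, aggregated as mean +/- SD with a coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .calibration import FitError, LambdaSpeedModel, SpeedLog, mean_speed
from .model import (
    AmbientConditions,
    CabinSpec,
    ParameterError,
    SensorTrace,
    kgen_to_vco2,
    stpd_correction_factor,
    weir_ee,
)

SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables for growth-cycle extraction.

    ``settle_s`` seconds after each RC switch are discarded to let the
    cabin re-mix; the change-point detector smooths the 1 Hz trace with a
    centered ``smooth_window_s`` moving average before looking for local
    extrema, since sensor noise is fast relative to the 5-12 min cycles.
    """

    min_duration_s: float = 120.0
    settle_s: float = 15.0
    smooth_window_s: float = 30.0
    min_growth_ppm: float = 50.0
    peak_prominence_ppm: float = 100.0


@dataclass
class GrowthCycle:
    """One RC-on CO2 accumulation interval of a trace."""

    start_s: float
    end_s: float
    samples: SensorTrace
    rc_state: bool = True
    mean_speed: float | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def net_growth(self) -> float:
        return float(self.samples.co2[-1] - self.samples.co2[0])


@dataclass
class CycleEstimate:
    """Per-cycle fit: generation rate, VCO2 and energy expenditure."""

    kgen: float
    kgen_se: float
    vco2: float
    ee: float
    lambda_used: float
    initial_offset: float
    r_squared: float
    residual_sd: float
    n_points: int
    start_s: float
    end_s: float
    mean_speed: float | None = None


@dataclass
class EEEstimate:
    """Aggregate energy-expenditure result over growth cycles.

    ``sd_ee`` uses the n-1 denominator; with a single cycle the SD and CV
    are undefined and reported as NaN rather than zero.
    """

    per_cycle: list[CycleEstimate]
    mean_ee: float
    sd_ee: float
    cv_percent: float
    n_occupants: int = 1
    per_occupant: bool = False


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def segment_growth_cycles(
    trace: SensorTrace,
    schedule: list[tuple[float, float]] | None = None,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[GrowthCycle]:
    """Extract CO2 growth cycles from a trace.

    With a known RC schedule, cycles are the RC-on intervals trimmed by the
    settling margin.  Without one, cycles are detected on a smoothed copy
    of the trace as runs from a local minimum to the next prominent local
    maximum.  Cycles shorter than the configured minimum or with
    insufficient net CO2 growth are dropped; an empty list is a legal
    result.
    """
    if schedule is not None:
        bounds = [(float(a), float(b)) for a, b in schedule]
    else:
        dt = float(np.median(np.diff(trace.timestamps))) if len(trace) > 1 else 1.0
        window = max(int(round(config.smooth_window_s / dt)), 1)
        smooth = _smooth(trace.co2, window)
        peaks, _ = find_peaks(smooth, prominence=config.peak_prominence_ppm)
        # the final growth may end at the trace boundary without a purge
        if smooth.size > 1 and (peaks.size == 0 or peaks[-1] < smooth.size - 1):
            tail = np.argmax(smooth[peaks[-1] :]) + peaks[-1] if peaks.size else int(np.argmax(smooth))
            if tail == smooth.size - 1 and smooth[-1] - np.min(smooth) >= config.peak_prominence_ppm:
                peaks = np.append(peaks, smooth.size - 1)
        bounds = []
        prev_peak = 0
        for pk in peaks:
            lo = prev_peak + int(np.argmin(smooth[prev_peak : pk + 1]))
            bounds.append((float(trace.timestamps[lo]), float(trace.timestamps[pk])))
            prev_peak = int(pk)

    cycles: list[GrowthCycle] = []
    for lo, hi in bounds:
        start = lo + config.settle_s
        if hi - start < config.min_duration_s:
            continue
        sub = trace.slice(start, hi)
        if len(sub) < 4:
            continue
        cycle = GrowthCycle(start_s=start, end_s=hi, samples=sub)
        if cycle.net_growth <= config.min_growth_ppm:
            continue
        cycles.append(cycle)
    return cycles


def attach_mean_speeds(cycles: list[GrowthCycle], log: SpeedLog) -> None:
    """Annotate each cycle with its time-weighted mean driving speed."""
    for c in cycles:
        lo = max(c.start_s, float(log.timestamps[0]))
        hi = min(c.end_s, float(log.timestamps[-1]))
        c.mean_speed = mean_speed(log, (lo, hi)) if hi > lo else float(log.speed[-1])


def fit_cycle_kgen(
    cycle: GrowthCycle, lam: float, baseline: float
) -> tuple[float, float, float, float, float]:
    """Fit K_gen and the initial offset with lambda and baseline fixed.

    The box-model solution is linear in (K_gen, CO2_i) once lambda is
    known, so the fit is an exact weighted-free linear least squares.
    Returns (kgen, kgen_se, initial_offset, r_squared, residual_sd).
    """
    t_h = (cycle.samples.timestamps - cycle.samples.timestamps[0]) / SECONDS_PER_HOUR
    y = cycle.samples.co2 - baseline
    if lam == 0.0:
        a1 = t_h
    else:
        a1 = -np.expm1(-lam * t_h) / lam
    a2 = np.exp(-lam * t_h)
    A = np.column_stack([a1, a2])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    resid = y - fitted
    n = y.size
    dof = max(n - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else float(np.clip(1.0 - float(resid @ resid) / ss_tot, 0.0, 1.0))
    return float(coef[0]), float(math.sqrt(max(cov[0, 0], 0.0))), float(coef[1]), r2, float(
        math.sqrt(sigma2)
    )


def estimate_cycle_ee(
    cycle: GrowthCycle,
    lambda_model: LambdaSpeedModel | float,
    cabin: CabinSpec = CabinSpec(),
    ambient: AmbientConditions = AmbientConditions(),
    rq: float = 0.85,
) -> CycleEstimate:
    """Per-cycle K_gen, VCO2 and energy expenditure.

    The air exchange rate is fixed from ``lambda_model`` evaluated at the
    cycle's mean driving speed (or given directly as a float); the STPD
    correction comes from ``ambient`` (1.0 at the STPD-reference default).
    """
    if len(cycle.samples) < 4:
        raise FitError(
            f"cycle [{cycle.start_s:.0f}, {cycle.end_s:.0f}] s has too few samples"
        )
    if isinstance(lambda_model, LambdaSpeedModel):
        if cycle.mean_speed is None:
            raise ParameterError(
                f"cycle [{cycle.start_s:.0f}, {cycle.end_s:.0f}] s lacks a mean speed"
            )
        lam = float(lambda_model.predict(cycle.mean_speed))
    else:
        lam = float(lambda_model)
    try:
        kgen, kgen_se, offset, r2, resid_sd = fit_cycle_kgen(
            cycle, lam, ambient.baseline_co2
        )
    except np.linalg.LinAlgError as err:
        raise FitError(
            f"cycle [{cycle.start_s:.0f}, {cycle.end_s:.0f}] s fit failed: {err}"
        ) from err
    cf = stpd_correction_factor(ambient)
    vco2 = kgen_to_vco2(max(kgen, 0.0), cabin, cf)
    return CycleEstimate(
        kgen=kgen,
        kgen_se=kgen_se,
        vco2=vco2,
        ee=weir_ee(vco2, rq),
        lambda_used=lam,
        initial_offset=offset,
        r_squared=r2,
        residual_sd=resid_sd,
        n_points=len(cycle.samples),
        start_s=cycle.start_s,
        end_s=cycle.end_s,
        mean_speed=cycle.mean_speed,
    )


def aggregate_ee(
    per_cycle: list[CycleEstimate], n_occupants: int = 1
) -> EEEstimate:
    """Mean, sample SD and CV% of per-cycle energy expenditure.

    With more than one occupant the totals are divided by the occupant
    count and the result flagged as a per-occupant average (individual
    EE is not identifiable from a shared cabin).
    """
    if not per_cycle:
        raise ParameterError("no cycles to aggregate")
    if n_occupants < 1:
        raise ParameterError("occupant count must be >= 1")
    values = np.array([c.ee for c in per_cycle]) / n_occupants
    mean = float(values.mean())
    if values.size >= 2:
        sd = float(values.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else math.nan
    else:
        sd = math.nan
        cv = math.nan
    return EEEstimate(
        per_cycle=per_cycle,
        mean_ee=mean,
        sd_ee=sd,
        cv_percent=cv,
        n_occupants=n_occupants,
        per_occupant=n_occupants > 1,
    )


def estimate_session_ee(
    trace: SensorTrace,
    lambda_model: LambdaSpeedModel | float,
    speed_log: SpeedLog | None = None,
    schedule: list[tuple[float, float]] | None = None,
    cabin: CabinSpec = CabinSpec(),
    ambient: AmbientConditions = AmbientConditions(),
    rq: float = 0.85,
    config: SegmentationConfig = SegmentationConfig(),
    n_occupants: int = 1,
) -> EEEstimate:
    """End-to-end pipeline: segment, fit each cycle, aggregate.

    ``speed_log`` is required when ``lambda_model`` is a speed model;
    with a plain float lambda it is optional.
    """
    cycles = segment_growth_cycles(trace, schedule=schedule, config=config)
    if not cycles:
        raise FitError("no usable growth cycles found in trace")
    if speed_log is not None:
        attach_mean_speeds(cycles, speed_log)
    elif isinstance(lambda_model, LambdaSpeedModel):
        raise ParameterError("a speed log is required to evaluate the lambda(speed) model")
    estimates = [
        estimate_cycle_ee(c, lambda_model, cabin=cabin, ambient=ambient, rq=rq)
        for c in cycles
    ]
    return aggregate_ee(estimates, n_occupants=n_occupants)
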