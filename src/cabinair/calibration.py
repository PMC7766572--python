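"""Calibration of the cabin CO2 box model from recirculation-mode drives.

Three stages:

1. ``fit_parked_kgen`` — at 0 MPH air leakage is negligible, so CO2 rises
   linearly and the slope of an ordinary least-squares line is the
   occupant generation rate K_gen [ppm/h].
2. ``fit_lambda`` — with K_gen known, the air exchange rate lambda of a
   growth segment at a given speed is recovered by nonlinear least squares
   on the closed-form box-model solution.
3. ``fit_lambda_speed_model`` — per-speed lambda estimates are regressed on
   mean driving speed, giving a piecewise model: a negligible constant
   floor below a threshold speed and a straight line above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import BoxModelParams, ParameterError, SensorTrace, co2_profile

SECONDS_PER_HOUR = 3600.0

#: lambda values below this are reported as negligible exchange [1/h].
NEGLIGIBLE_LAMBDA = 1e-6


class FitError(RuntimeError):
    """A regression could not be computed or did not converge."""


@dataclass
class FitResult:
    """Outcome of a single-parameter fit.

    ``estimate`` and ``standard_error`` share the parameter's units;
    ``r_squared`` is 1 - SS_res/SS_tot about the trace mean, clipped to
    [0, 1]; ``params`` carries co-estimated nuisance parameters.
    """

    estimate: float
    standard_error: float
    r_squared: float
    n_points: int
    residual_sd: float
    params: dict = field(default_factory=dict)
    note: str = ""


@dataclass(frozen=True)
class LambdaSpeedModel:
    """Piecewise air-exchange-rate vs driving-speed relationship.

    Above ``threshold_speed`` [MPH] the rate follows the fitted line
    ``slope * speed + intercept`` (clipped from below at the floor); at or
    below the threshold the intrinsic exchange is negligible and the
    constant ``lambda_below_threshold`` applies.  The two regimes are
    disjoint; continuity at the threshold is not imposed.
    """

    slope: float = 0.060
    intercept: float = -0.88
    threshold_speed: float = 17.5
    lambda_below_threshold: float = 0.05
    r_squared: float | None = None
    slope_se: float | None = None

    def predict(self, speed):
        """Air exchange rate [1/h] at ``speed`` [MPH] (scalar or array)."""
        speed = np.asarray(speed, dtype=float)
        if np.any(speed < 0):
            raise ParameterError("speed must be >= 0")
        line = np.maximum(self.slope * speed + self.intercept, self.lambda_below_threshold)
        out = np.where(speed > self.threshold_speed, line, self.lambda_below_threshold)
        return float(out) if out.ndim == 0 else out


#: The published piecewise relationship for a closed-window mid-size sedan:
#: lambda = 0.060 * speed - 0.88 above ~17 MPH, negligible (0.05 1/h) below.
DEFAULT_LAMBDA_SPEED_MODEL = LambdaSpeedModel()


@dataclass
class SpeedLog:
    """Driving-speed recording: seconds from start and speed in MPH."""

    timestamps: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.timestamps.size != self.speed.size:
            raise ParameterError("speed log columns have mismatched lengths")
        if self.timestamps.size >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ParameterError("speed log timestamps not strictly increasing")
        if np.any(self.speed < 0):
            raise ParameterError("speed must be >= 0")


def _r_squared(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def fit_parked_kgen(trace: SensorTrace, min_duration_s: float = 300.0) -> FitResult:
    """Generation rate K_gen [ppm/h] from a parked (0 MPH) recording.

    Ordinary least-squares slope of CO2 against time in hours.  The
    intercept estimates baseline + initial offset and is reported under
    ``params['intercept']``.
    """
    if len(trace) < 3:
        raise FitError(f"need at least 3 samples, got {len(trace)}")
    if trace.duration_s <= 0:
        raise FitError("trace has zero time span")
    if trace.duration_s < min_duration_s:
        import warnings

        warnings.warn(
            f"parked trace spans {trace.duration_s:.0f} s, shorter than the "
            f"recommended {min_duration_s:.0f} s",
            stacklevel=2,
        )
    t_h = (trace.timestamps - trace.timestamps[0]) / SECONDS_PER_HOUR
    res = stats.linregress(t_h, trace.co2)
    fitted = res.intercept + res.slope * t_h
    n = len(trace)
    resid_sd = float(np.sqrt(np.sum((trace.co2 - fitted) ** 2) / max(n - 2, 1)))
    return FitResult(
        estimate=float(res.slope),
        standard_error=float(res.stderr),
        r_squared=_r_squared(trace.co2, fitted),
        n_points=n,
        residual_sd=resid_sd,
        params={"intercept": float(res.intercept), "intercept_se": float(res.intercept_stderr)},
    )


_LAMBDA_STARTS = (1.0, 0.1, 0.5, 2.0, 5.0, 10.0)
LAMBDA_BOUNDS = (0.0, 50.0)


def fit_lambda(
    trace: SensorTrace,
    kgen_known: float | None,
    baseline: float = 400.0,
    bounds: tuple[float, float] = LAMBDA_BOUNDS,
) -> FitResult:
    """Air exchange rate lambda [1/h] from a CO2 growth segment.

    When ``kgen_known`` is given it is held fixed and (lambda, CO2_i) are
    estimated; with ``kgen_known=None`` all of (lambda, K_gen, CO2_i) are
    free, which is poorly identified on short low-lambda segments and is
    provided mainly for diagnostics.  Up to six starting values of lambda
    are tried; the best converged fit (lowest residual sum of squares)
    wins.  A lambda estimate at the lower bound is annotated as
    negligible exchange.
    """
    if len(trace) < 4:
        raise FitError(f"need at least 4 samples, got {len(trace)}")
    t_h = (trace.timestamps - trace.timestamps[0]) / SECONDS_PER_HOUR
    y = trace.co2
    offset0 = float(y[0] - baseline)

    if kgen_known is not None:
        if kgen_known <= 0:
            raise ParameterError(f"known K_gen must be positive, got {kgen_known}")

        def f(t, lam, offset):
            return co2_profile(t, BoxModelParams(baseline, offset, kgen_known, lam))

        p_lo, p_hi = [bounds[0], -np.inf], [bounds[1], np.inf]

        def make_p0(lam0):
            return [lam0, offset0]

    else:
        kgen0 = max(float((y[-1] - y[0]) / max(t_h[-1], 1e-9)), 1.0)

        def f(t, lam, kgen, offset):
            return co2_profile(t, BoxModelParams(baseline, offset, kgen, lam))

        p_lo, p_hi = [bounds[0], 0.0, -np.inf], [bounds[1], np.inf, np.inf]

        def make_p0(lam0):
            return [lam0, kgen0, offset0]

    best = None
    last_err: Exception | None = None
    for lam0 in _LAMBDA_STARTS:
        try:
            popt, pcov = optimize.curve_fit(
                f, t_h, y, p0=make_p0(lam0), bounds=(p_lo, p_hi), maxfev=20000
            )
        except (RuntimeError, ValueError) as err:  # non-convergence for this start
            last_err = err
            continue
        ssr = float(np.sum((y - f(t_h, *popt)) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise FitError(f"lambda fit did not converge from any start: {last_err}")

    popt, pcov, ssr = best
    fitted = f(t_h, *popt)
    n = len(trace)
    dof = max(n - len(popt), 1)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    se = np.where(np.isfinite(se), se, np.inf)
    lam_hat = float(popt[0])
    note = "negligible exchange" if lam_hat <= bounds[0] + NEGLIGIBLE_LAMBDA else ""
    params = {"initial_offset": float(popt[-1]), "initial_offset_se": float(se[-1])}
    if kgen_known is None:
        params.update({"generation_rate": float(popt[1]), "generation_rate_se": float(se[1])})
    return FitResult(
        estimate=lam_hat,
        standard_error=float(se[0]),
        r_squared=_r_squared(y, fitted),
        n_points=n,
        residual_sd=float(np.sqrt(ssr / dof)),
        params=params,
        note=note,
    )


def fit_lambda_speed_model(
    points,
    threshold: float = 17.5,
    lambda_floor: float = 0.05,
) -> LambdaSpeedModel:
    """Piecewise lambda(speed) model from (mean speed [MPH], lambda [1/h]) pairs.

    Points strictly above ``threshold`` enter an ordinary least-squares
    line; points at or below it are excluded (they belong to the
    negligible-exchange regime represented by ``lambda_floor``).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("points must be (speed, lambda) pairs")
    above = pts[pts[:, 0] > threshold]
    if above.shape[0] < 2:
        raise FitError(
            f"need at least 2 points above {threshold} MPH, got {above.shape[0]}"
        )
    x, y = above[:, 0], above[:, 1]
    if above.shape[0] == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2, slope_se = 1.0, 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = _r_squared(y, intercept + slope * x)
        slope_se = float(res.stderr)
    return LambdaSpeedModel(
        slope=float(slope),
        intercept=float(intercept),
        threshold_speed=threshold,
        lambda_below_threshold=lambda_floor,
        r_squared=r2,
        slope_se=slope_se,
    )


def mean_speed(log: SpeedLog, window: tuple[float, float] | None = None) -> float:
    """Time-weighted mean speed [MPH] over ``window`` (seconds into the log).

    Trapezoidal integration over the (possibly irregular) samples; window
    endpoints falling between samples are linearly interpolated.
    """
    t, v = log.timestamps, log.speed
    if window is None:
        lo, hi = float(t[0]), float(t[-1])
    else:
        lo, hi = float(window[0]), float(window[1])
    if not (t[0] <= lo < hi <= t[-1]):
        raise ParameterError(f"window [{lo}, {hi}] outside log span [{t[0]}, {t[-1]}]")
    inner = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inner], [hi]))
    vv = np.concatenate(([np.interp(lo, t, v)], v[inner], [np.interp(hi, t, v)]))
    return float(np.trapezoid(vv, tt) / (hi - lo))
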