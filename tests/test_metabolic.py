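"""Growth-cycle segmentation and per-cycle energy-expenditure estimation."""

import math

import numpy as np
import pytest

from cabinair import (
    AmbientConditions,
    CabinSpec,
    GrowthCycle,
    NoiseModel,
    ParameterError,
    SegmentationConfig,
    SensorTrace,
    aggregate_ee,
    attach_mean_speeds,
    estimate_cycle_ee,
    estimate_session_ee,
    generate_method2_session,
    segment_growth_cycles,
)
from cabinair.calibration import DEFAULT_LAMBDA_SPEED_MODEL, FitError
from cabinair.metabolic import fit_cycle_kgen
from cabinair.model import BoxModelParams, co2_profile, occupant_generation_rate, OccupantProfile


def growth_trace(kgen, lam, duration_s=600.0, baseline=400.0, offset=50.0, sd=0.0, seed=0):
    t = np.arange(0.0, duration_s + 1.0)
    co2 = co2_profile(t / 3600.0, BoxModelParams(baseline, offset, kgen, lam))
    if sd > 0:
        co2 = co2 + np.random.default_rng(seed).normal(0.0, sd, t.size)
    return SensorTrace(t, co2)


class TestSegmentation:
    def test_scheduled_cycles_trimmed_by_settle_margin(self, parked_session):
        cfg = SegmentationConfig()
        cycles = segment_growth_cycles(parked_session.trace, schedule=parked_session.schedule, config=cfg)
        assert len(cycles) == 4
        for cyc, (lo, hi) in zip(cycles, parked_session.schedule):
            assert cyc.start_s == pytest.approx(lo + cfg.settle_s)
            assert cyc.end_s == pytest.approx(hi)
            assert cyc.net_growth > 0

    def test_detector_recovers_scheduled_boundaries(self, parked_session):
        cfg = SegmentationConfig()
        cycles = segment_growth_cycles(parked_session.trace, config=cfg)
        assert len(cycles) == 4
        for cyc, (lo, hi) in zip(cycles, parked_session.schedule):
            assert abs(cyc.start_s - (lo + cfg.settle_s)) <= 20.0
            assert abs(cyc.end_s - hi) <= 20.0

    def test_constant_trace_yields_no_cycles(self):
        trace = SensorTrace(np.arange(0.0, 3600.0), np.full(3600, 450.0))
        assert segment_growth_cycles(trace) == []

    def test_short_or_flat_scheduled_intervals_dropped(self, parked_session):
        schedule = [(0.0, 60.0)]  # shorter than the minimum duration
        assert segment_growth_cycles(parked_session.trace, schedule=schedule) == []

    def test_time_shift_invariance(self, parked_session):
        trace = parked_session.trace
        shifted = SensorTrace(
            trace.timestamps + 500.0, trace.co2, trace.temperature, trace.relative_humidity
        )
        a = segment_growth_cycles(trace)
        b = segment_growth_cycles(shifted)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert cb.start_s - ca.start_s == pytest.approx(500.0, abs=1e-6)
            assert cb.end_s - ca.end_s == pytest.approx(500.0, abs=1e-6)


class TestCycleEstimate:
    def test_noiseless_parked_cycle_recovers_ee(self):
        cabin = CabinSpec(3.1)
        kgen = occupant_generation_rate(OccupantProfile(1620.0, 0.85), cabin)
        trace = growth_trace(kgen, 0.05)
        cycle = GrowthCycle(0.0, 600.0, trace, mean_speed=0.0)
        est = estimate_cycle_ee(cycle, 0.05, cabin=cabin)
        assert est.ee == pytest.approx(1620.0, rel=1e-3)
        assert est.r_squared > 0.999

    def test_hand_chain_kgen_to_ee(self):
        # K_gen 5344 ppm/h in 3.1 m^3 at CF 0.851: VCO2 = 235.0 mL/min, EE = 1944
        trace = growth_trace(5344.0, 0.05)
        cycle = GrowthCycle(0.0, 600.0, trace, mean_speed=0.0)
        ambient = AmbientConditions(730.0, 23.8, 25.0)  # CF ~ 0.8512
        est = estimate_cycle_ee(cycle, 0.05, cabin=CabinSpec(3.1), ambient=ambient)
        assert est.vco2 == pytest.approx(235.0, abs=0.5)
        assert est.ee == pytest.approx(1944.0, abs=5.0)

    def test_noisy_cycles_mean_within_ten_percent(self):
        cabin = CabinSpec(3.1)
        kgen = occupant_generation_rate(OccupantProfile(1620.0, 0.85), cabin)
        ees = []
        for seed in range(50):
            trace = growth_trace(kgen, 2.12, duration_s=300.0, sd=15.0, seed=seed)
            cycle = GrowthCycle(0.0, 300.0, trace, mean_speed=50.0)
            ees.append(estimate_cycle_ee(cycle, DEFAULT_LAMBDA_SPEED_MODEL, cabin=cabin).ee)
        assert np.mean(ees) == pytest.approx(1620.0, rel=0.10)

    def test_linear_fit_matches_generating_parameters_exactly(self):
        trace = growth_trace(4500.0, 1.3, offset=75.0)
        cycle = GrowthCycle(0.0, 600.0, trace)
        kgen, kgen_se, offset, r2, resid = fit_cycle_kgen(cycle, 1.3, 400.0)
        assert kgen == pytest.approx(4500.0, rel=1e-9)
        assert offset == pytest.approx(75.0, abs=1e-6)
        assert resid == pytest.approx(0.0, abs=1e-6)

    def test_speed_model_requires_mean_speed(self):
        trace = growth_trace(4000.0, 0.05)
        cycle = GrowthCycle(0.0, 600.0, trace, mean_speed=None)
        with pytest.raises(ParameterError):
            estimate_cycle_ee(cycle, DEFAULT_LAMBDA_SPEED_MODEL)


class TestAggregate:
    def test_identical_values(self):
        cycles = [_fake_cycle(1600.0) for _ in range(4)]
        agg = aggregate_ee(cycles)
        assert agg.mean_ee == pytest.approx(1600.0)
        assert agg.sd_ee == pytest.approx(0.0)
        assert agg.cv_percent == pytest.approx(0.0)

    def test_sample_sd_and_cv(self):
        cycles = [_fake_cycle(v) for v in (1420.0, 1550.0, 1680.0, 1730.0)]
        agg = aggregate_ee(cycles)
        assert agg.mean_ee == pytest.approx(1595.0)
        assert agg.sd_ee == pytest.approx(139.2, abs=0.5)
        assert agg.cv_percent == pytest.approx(8.7, abs=0.1)

    def test_single_cycle_sd_undefined_not_zero(self):
        agg = aggregate_ee([_fake_cycle(1500.0)])
        assert agg.mean_ee == pytest.approx(1500.0)
        assert math.isnan(agg.sd_ee)
        assert math.isnan(agg.cv_percent)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_ee([])

    def test_multi_occupant_reports_per_occupant_average(self):
        cycles = [_fake_cycle(3200.0) for _ in range(4)]
        agg = aggregate_ee(cycles, n_occupants=2)
        assert agg.mean_ee == pytest.approx(1600.0)
        assert agg.per_occupant


def _fake_cycle(ee):
    from cabinair.metabolic import CycleEstimate

    return CycleEstimate(
        kgen=0.0, kgen_se=0.0, vco2=0.0, ee=ee, lambda_used=0.05, initial_offset=0.0,
        r_squared=1.0, residual_sd=0.0, n_points=100, start_s=0.0, end_s=300.0,
    )


class TestEndToEnd:
    def test_noisy_session_recovers_ee_within_envelope(self):
        """Full pipeline bias <= 5% and cycle-to-cycle CV <= 15%."""
        biases, cvs = [], []
        for seed in range(5):
            session = generate_method2_session(
                ee_true=1620.0, speed=0.0, n_cycles=4, noise=NoiseModel(gaussian_sd=15.0, seed=seed)
            )
            result = estimate_session_ee(
                session.trace,
                DEFAULT_LAMBDA_SPEED_MODEL,
                speed_log=session.speed_log,
                schedule=session.schedule,
            )
            biases.append(result.mean_ee / 1620.0 - 1.0)
            cvs.append(result.cv_percent)
        assert abs(np.mean(biases)) <= 0.05
        assert max(cvs) <= 15.0

    def test_ee_invariant_to_vehicle_speed(self):
        """When the generator's lambda follows the speed model and the pipeline
        uses the same model, the recovered EE does not depend on speed."""
        means = []
        for speed in (0.0, 33.0, 64.0):
            session = generate_method2_session(
                ee_true=1620.0, speed=speed, n_cycles=4,
                noise=NoiseModel(gaussian_sd=0.0, quantization=0.0, seed=0),
                speed_jitter_sd=0.0,
            )
            result = estimate_session_ee(
                session.trace,
                DEFAULT_LAMBDA_SPEED_MODEL,
                speed_log=session.speed_log,
                schedule=session.schedule,
            )
            means.append(result.mean_ee)
        assert np.ptp(means) / np.mean(means) < 0.01

    def test_detector_path_equivalent_to_schedule_path(self, parked_session):
        by_schedule = estimate_session_ee(
            parked_session.trace, 0.05, speed_log=parked_session.speed_log,
            schedule=parked_session.schedule,
        )
        by_detector = estimate_session_ee(
            parked_session.trace, 0.05, speed_log=parked_session.speed_log
        )
        assert by_detector.mean_ee == pytest.approx(by_schedule.mean_ee, rel=0.03)

    def test_empty_trace_raises_fit_error(self):
        trace = SensorTrace(np.arange(0.0, 1200.0), np.full(1200, 450.0))
        with pytest.raises(FitError):
            estimate_session_ee(trace, 0.05)
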