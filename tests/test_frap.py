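"""FRAP analysis: recovery normalization, quadrant symmetry, centroid
tracking and the null-calibrated velocity bound."""

import numpy as np
import pytest

from conftest import stack_from_sim
from ecstransport import (
    BleachSpec,
    CentroidTrace,
    DegenerateInputError,
    ImageStack,
    InvalidParameterError,
    NoiseModel,
    TransportParams,
    compare_halftimes,
    distal_timecourses,
    effect_size,
    make_frap_stack,
    quadrant_recovery,
    recovery_curve,
    register_stack,
    simulate_frap,
    track_centroid,
    velocity_upper_bound,
)


def make_trace(displacements_um, dt=1.0):
    """Straight-line trace along +x with the given per-frame positions."""
    pos = np.zeros((len(displacements_um), 2))
    pos[:, 0] = displacements_um
    return CentroidTrace(times=np.arange(len(pos)) * dt, positions=pos)


class TestRecoveryCurve:
    def test_unbleached_stack_is_degenerate(self):
        frames = np.full((6, 40, 40), 7.0)
        stack = ImageStack(frames, pixel_size=1.0, frame_interval=1.0, prebleach_count=2)
        with pytest.raises(DegenerateInputError):
            recovery_curve(stack, (20.0, 20.0), 10.0)

    def test_t_half_absent_when_recovery_incomplete(self, coarse_grid):
        frames, _, info = simulate_frap(
            TransportParams(D=0.05), BleachSpec(), duration=5.0, frame_interval=1.0, grid=coarse_grid
        )
        stack = stack_from_sim(frames, info, 1.0)
        assert recovery_curve(stack, (50.0, 50.0), 10.0).t_half is None

    def test_roi_outside_image_rejected(self, noiseless_null_stack):
        with pytest.raises(InvalidParameterError):
            recovery_curve(noiseless_null_stack, (2.0, 50.0), 10.0)

    def test_rotation_invariance_of_recovery(self, noiseless_null_stack):
        base = recovery_curve(noiseless_null_stack, (50.0, 50.0), 10.0)
        rot = ImageStack(
            np.rot90(noiseless_null_stack.frames, axes=(1, 2)).copy(),
            pixel_size=noiseless_null_stack.pixel_size,
            frame_interval=noiseless_null_stack.frame_interval,
            prebleach_count=noiseless_null_stack.prebleach_count,
        )
        rcurve = recovery_curve(rot, (50.0, 50.0), 10.0)
        assert np.sqrt(np.mean((base.F - rcurve.F) ** 2)) < 0.01


class TestQuadrants:
    def test_isotropic_recovery_gives_zero_asymmetry(self, noiseless_null_stack):
        curves, index = quadrant_recovery(noiseless_null_stack, (50.0, 50.0), 10.0)
        t_halves = [c.t_half for c in curves]
        assert index == pytest.approx(0.0, abs=1e-9)
        assert max(t_halves) - min(t_halves) == pytest.approx(0.0, abs=1e-9)

    def test_flow_makes_upstream_sector_recover_first(self, coarse_grid):
        # flow along +x: sector 3 (containing the -x upstream half... the
        # upstream supply arrives from -x) is refilled by unbleached fluid
        frames, _, info = simulate_frap(
            TransportParams(D=1.0, v=(30.0, 0.0)),
            BleachSpec(),
            duration=30.0,
            frame_interval=0.5,
            grid=coarse_grid,
        )
        stack = stack_from_sim(frames, info, 0.5)
        curves, index = quadrant_recovery(stack, (50.0, 50.0), 10.0)
        assert index > 0.05
        t = {c.label: c.t_half for c in curves}
        # sectors 1 and 2 straddle +y/-y; upstream-facing halves are
        # Q1/Q2 vs downstream Q0/Q3 split by the x axis: with flow to +x
        # the sector pair containing -x (Q1, Q2) recovers earlier
        upstream = 0.5 * (t["Q1"] + t["Q2"])
        downstream = 0.5 * (t["Q0"] + t["Q3"])
        assert upstream < downstream

    def test_rotating_stack_permutes_sector_half_times(self, coarse_grid):
        frames, _, info = simulate_frap(
            TransportParams(D=1.0, v=(20.0, 0.0)),
            BleachSpec(),
            duration=30.0,
            frame_interval=0.5,
            grid=coarse_grid,
        )
        stack = stack_from_sim(frames, info, 0.5)
        curves, _ = quadrant_recovery(stack, (50.0, 50.0), 10.0)
        rot = ImageStack(
            np.rot90(stack.frames, axes=(1, 2)).copy(),
            pixel_size=stack.pixel_size,
            frame_interval=stack.frame_interval,
            prebleach_count=stack.prebleach_count,
        )
        rcurves, _ = quadrant_recovery(rot, (50.0, 50.0), 10.0)
        a = sorted(c.t_half for c in curves)
        b = sorted(c.t_half for c in rcurves)
        np.testing.assert_allclose(a, b, rtol=0.02)


class TestDistalTimecourses:
    def test_center_window_mirrors_dip_and_distal_dip_is_shallower(self, coarse_grid):
        frames, _, info = simulate_frap(
            TransportParams(D=2.0), BleachSpec(), duration=30.0, frame_interval=0.5, grid=coarse_grid
        )
        stack = stack_from_sim(frames, info, 0.5)
        center, distal = distal_timecourses(stack, [(50.0, 50.0), (70.0, 50.0)])
        assert center.F.min() < 0.6  # bleached floor at the spot
        assert distal.F.min() > center.F.min()
        assert distal.F.min() < 1.0  # transient dip as bleached molecules arrive

    def test_window_clipped_by_border_rejected(self, noiseless_null_stack):
        with pytest.raises(InvalidParameterError):
            distal_timecourses(noiseless_null_stack, [(0.5, 50.0)])


class TestTrackCentroid:
    def test_pure_translation_gives_linear_displacement(self):
        # dark spot marching 2 um per frame across a textured background
        rng = np.random.default_rng(3)
        h = w = 80
        base = 100.0 + 10.0 * rng.standard_normal((h, w))
        ys, xs = np.mgrid[0:h, 0:w]
        frames = [base.copy(), base.copy()]
        for k in range(6):
            cx = 20.0 + 2.0 * k
            spot = 50.0 * np.exp(-(((xs - cx) ** 2) + (ys - 40.0) ** 2) / (2 * 3.0**2))
            frames.append(base - spot)
        stack = ImageStack(np.array(frames), pixel_size=1.0, frame_interval=1.0, prebleach_count=2)
        trace = track_centroid(stack, scan_diameter=10.0)
        slopes = np.diff(trace.positions[:, 0])
        np.testing.assert_allclose(slopes, 2.0, atol=0.3)

    def test_noiseless_null_stays_put(self, noiseless_null_stack):
        trace = track_centroid(noiseless_null_stack)
        np.testing.assert_allclose(trace.displacement, 0.0, atol=1e-9)

    def test_no_bleach_is_degenerate(self):
        frames = np.full((5, 40, 40), 5.0)
        stack = ImageStack(frames, pixel_size=1.0, frame_interval=1.0, prebleach_count=2)
        with pytest.raises(DegenerateInputError):
            track_centroid(stack)

    def test_velocity_recovered_within_15_percent(self):
        # parameter recovery: 3 um/min flow, default SNR, a few seeds
        speeds = []
        for seed in range(4):
            stack = make_frap_stack(
                params=TransportParams(D=0.4, v=(3.0, 0.0)),
                noise=NoiseModel(seed=seed),
                duration=60.0,
            )
            speeds.append(track_centroid(stack).fitted_velocity()[0])
        assert np.mean(speeds) == pytest.approx(3.0, rel=0.15)


class TestVelocityBound:
    def test_zero_nulls_give_zero_bound(self):
        nulls = [make_trace(np.zeros(61)) for _ in range(12)]
        bound, flag = velocity_upper_bound(None, nulls)
        assert bound == 0.0
        assert flag is None

    def test_bound_arithmetic_one_um_over_one_minute(self):
        nulls = [make_trace(np.linspace(0, 1.0, 61)) for _ in range(12)]
        bound, _ = velocity_upper_bound(None, nulls)
        assert bound == pytest.approx(1.0)

    def test_directional_flag(self):
        nulls = [make_trace(np.linspace(0, 1.0, 61)) for _ in range(12)]
        fast = make_trace(np.linspace(0, 5.0, 61))
        _, flag = velocity_upper_bound(fast, nulls)
        assert flag is True

    def test_requires_ten_nulls(self):
        with pytest.raises(InvalidParameterError):
            velocity_upper_bound(None, [make_trace(np.zeros(5))] * 5)

    def test_bound_decreases_with_snr(self):
        # 1/sqrt(photons) trend: higher photon budget -> tighter bound
        bounds = []
        for scale in (25.0, 100.0, 400.0):
            traces = []
            for seed in range(10):
                stack = make_frap_stack(
                    noise=NoiseModel(photon_scale=scale, seed=100 + seed), duration=30.0
                )
                traces.append(track_centroid(stack))
            bounds.append(velocity_upper_bound(None, traces)[0])
        assert bounds[0] > bounds[1] > bounds[2]


class TestStatsHelpers:
    def test_identical_groups_p_near_one(self):
        curves = lambda: [  # noqa: E731
            type("C", (), {"t_half": v})() for v in (10.0, 12.0, 14.0)
        ]
        out = compare_halftimes([curves(), curves()])
        assert out["t_test"]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_separated_groups_significant(self):
        g1 = [type("C", (), {"t_half": v})() for v in (10.0, 10.1, 9.9)]
        g2 = [type("C", (), {"t_half": v})() for v in (100.0, 100.2, 99.8)]
        out = compare_halftimes([g1, g2])
        assert out["t_test"]["p"] < 1e-3

    def test_effect_size_values(self):
        assert effect_size(25.0, 10.0) == 2.5
        assert effect_size(0.0, 10.0) == 0.0
        assert effect_size(30.0, 15.0) == 2.0
        with pytest.raises(InvalidParameterError):
            effect_size(25.0, 0.0)


class TestRegistration:
    def test_registration_halves_jitter_noise(self):
        # heartbeat-like 1 um rigid jitter on textured tissue; pooled
        # early-frame centroid noise must drop >= 2x after registration
        raw_sq, reg_sq = [], []
        for seed in (11, 12, 13):
            stack = make_frap_stack(
                noise=NoiseModel(jitter_sd=1.0, seed=seed),
                duration=20.0,
                texture_amplitude=0.2,
            )
            raw_sq.extend(track_centroid(stack).displacement[1:11] ** 2)
            reg_sq.extend(track_centroid(register_stack(stack)).displacement[1:11] ** 2)
        ratio = np.sqrt(np.mean(raw_sq) / np.mean(reg_sq))
        assert ratio >= 2.0
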