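"""Closed-form diffusion models: values checked against independent
numerical oracles (finite differences, bisection) and exact scalings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfcinv

from ecstransport import (
    InvalidParameterError,
    SpatialProfile,
    Tracer,
    TransportParams,
    alpha_adjusted_uptake,
    decay_distance,
    effective_diffusion,
    halfspace_profile,
    point_source_profile,
    relative_penetration,
)
from ecstransport.units import cm2_per_s_to_um2_per_s, um2_per_s_to_cm2_per_s


def fd_halfspace_oracle(D, t_end, depths, n=4000, L=None):
    """Brute-force 1-D explicit finite-difference integration of the
    diffusion equation with a clamped unit surface concentration —
    independent of the package's own solver."""
    L = L or max(depths) * 2.5
    dx = L / n
    c = np.zeros(n + 1)
    c[0] = 1.0
    dt = 0.2 * dx**2 / D
    steps = int(np.ceil(t_end / dt))
    dt = t_end / steps
    r = D * dt / dx**2
    for _ in range(steps):
        c[1:-1] += r * (c[2:] - 2 * c[1:-1] + c[:-2])
        c[0], c[-1] = 1.0, 0.0
    x = np.arange(n + 1) * dx
    return np.interp(depths, x, c)


class TestHalfspaceProfile:
    def test_surface_value_is_one_and_monotone(self):
        prof = halfspace_profile(TransportParams(D=51.0), 3600.0, np.linspace(0, 2000, 200))
        assert prof.intensities[0] == 1.0
        assert np.all(np.diff(prof.intensities) <= 0)

    def test_matches_finite_difference_oracle(self):
        D, t = 51.0, 600.0
        depths = np.linspace(0, 800, 60)
        prof = halfspace_profile(TransportParams(D=D), t, depths)
        oracle = fd_halfspace_oracle(D, t, depths)
        assert np.sqrt(np.mean((prof.intensities - oracle) ** 2)) < 1e-3

    def test_deep_limit_is_zero(self):
        prof = halfspace_profile(TransportParams(D=1.0), 60.0, [0.0, 1e5])
        assert prof.intensities[-1] == pytest.approx(0.0, abs=1e-12)

    def test_bolus_source_is_gaussian(self):
        D, t = 10.0, 100.0
        depths = np.linspace(0, 200, 50)
        prof = halfspace_profile(TransportParams(D=D), t, depths, source="bolus")
        np.testing.assert_allclose(prof.intensities, np.exp(-depths**2 / (4 * D * t)))

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            halfspace_profile(TransportParams(D=1.0), -1.0, [0.0, 1.0])
        with pytest.raises(InvalidParameterError):
            TransportParams(D=-1.0)
        with pytest.raises(InvalidParameterError):
            halfspace_profile(TransportParams(D=1.0), 1.0, [0.0, -5.0])


class TestDecayDistance:
    def test_half_decay_of_10kda_dextran_at_60min(self):
        # D = 5.1e-7 cm^2/s = 51 um^2/s; closed form 2 sqrt(D t) erfcinv(1/2)
        d = decay_distance(TransportParams(D=51.0), 3600.0, 0.5)
        assert d == pytest.approx(2 * np.sqrt(51 * 3600) * erfcinv(0.5), abs=1e-2)
        assert d == pytest.approx(408.7, abs=0.5)

    def test_sqrt_d_ratio_between_dextrans(self):
        d70 = decay_distance(TransportParams(D=7.5), 3600.0, 0.5)
        d10 = decay_distance(TransportParams(D=51.0), 3600.0, 0.5)
        assert d70 / d10 == pytest.approx(np.sqrt(7.5 / 51), rel=1e-6)

    def test_quadrupling_time_doubles_distance(self):
        p = TransportParams(D=3.0)
        assert decay_distance(p, 4 * 900.0, 0.3) == pytest.approx(
            2 * decay_distance(p, 900.0, 0.3), rel=1e-6
        )

    def test_strictly_decreasing_in_fraction_and_sqrt_dt_scaling(self):
        p = TransportParams(D=5.0)
        fractions = [0.1, 0.3, 0.5, 0.7, 0.9]
        ds = [decay_distance(p, 100.0, f) for f in fractions]
        assert all(a > b for a, b in zip(ds, ds[1:]))
        for scale in (2.0, 5.0):
            assert decay_distance(TransportParams(D=5.0 * scale), 100.0, 0.5) == pytest.approx(
                np.sqrt(scale) * ds[2], rel=1e-6
            )

    def test_fraction_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            decay_distance(TransportParams(D=1.0), 10.0, 1.5)


class TestPointSource:
    def test_normalized_at_origin_and_r10(self):
        D, t = 51.0, 3600.0
        prof = point_source_profile(TransportParams(D=D), t, np.linspace(0, 2000, 400))
        assert prof.intensities[0] == 1.0
        r10 = prof.decay_distance(0.1)
        assert r10 == pytest.approx(np.sqrt(4 * D * t * np.log(10)), rel=5e-3)
        assert r10 == pytest.approx(1300.0, rel=5e-3)

    def test_r10_sqrt_t_scaling(self):
        # 10 min vs 60 min sections: ratio 1/sqrt(6)
        r_short = np.sqrt(4 * 51 * 600 * np.log(10))
        r_long = np.sqrt(4 * 51 * 3600 * np.log(10))
        assert r_short / r_long == pytest.approx(1 / np.sqrt(6), rel=1e-12)

    def test_matches_radial_finite_difference_oracle(self):
        # spherically symmetric FD integration of the 3-D diffusion eq.
        D, t_end = 5.0, 50.0
        n, L = 1200, 400.0
        dr = L / n
        r = (np.arange(n) + 0.5) * dr
        t0 = 5.0  # start from the analytic profile at t0, advance to t_end
        c = (4 * np.pi * D * t0) ** -1.5 * np.exp(-(r**2) / (4 * D * t0))
        dt = 0.2 * dr**2 / D
        steps = int(np.ceil((t_end - t0) / dt))
        dt = (t_end - t0) / steps
        for _ in range(steps):
            flux = np.zeros(n + 1)
            r_face = np.arange(1, n) * dr
            flux[1:-1] = -D * (c[1:] - c[:-1]) / dr * r_face**2
            dcdt = -(flux[1:] - flux[:-1]) / (r**2 * dr)
            c = c + dt * dcdt
        prof = point_source_profile(TransportParams(D=D), t_end, np.concatenate([[0.0], r]))
        analytic = prof.intensities[1:] / prof.intensities[1]
        oracle = c / c[0]
        assert np.sqrt(np.mean((analytic - oracle) ** 2)) < 1e-3


class TestEffectiveDiffusion:
    def test_identity_and_arithmetic(self):
        assert effective_diffusion(7.0, 1.0) == 7.0
        assert effective_diffusion(10.0, 2.0) == 2.5

    def test_tortuosity_2_64_reproduces_2000kda_estimate(self):
        # free-solution D of the 2000 kDa dextran scaled by lambda = 2.64
        # gives the 0.1e-7 cm^2/s (= 1 um^2/s) tissue value
        assert effective_diffusion(6.97, 2.64) == pytest.approx(1.0, abs=1e-3)

    def test_lambda_below_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            effective_diffusion(1.0, 0.8)

    @settings(deadline=None, max_examples=50)
    @given(
        d=st.floats(1e-3, 1e3),
        l1=st.floats(1.0, 10.0),
        l2=st.floats(1.0, 10.0),
    )
    def test_multiplicative_in_tortuosity(self, d, l1, l2):
        a = effective_diffusion(d, l1 * l2)
        b = effective_diffusion(effective_diffusion(d, l1), l2)
        assert a == pytest.approx(b, rel=1e-12)


class TestRelativePenetration:
    def test_dextran_panel_ratios(self):
        tracers = [
            Tracer("10k", 10, 2, D_ecs=51.0),
            Tracer("70k", 70, 5, D_ecs=7.5),
            Tracer("2000k", 2000, 12, D_ecs=1.0),
        ]
        rel = relative_penetration(tracers)
        np.testing.assert_allclose(rel, [1.0, 0.3835, 0.1400], atol=5e-4)

    def test_single_tracer_and_time_independence(self):
        tr = [Tracer("a", 1, 1, D_ecs=3.0)]
        np.testing.assert_allclose(relative_penetration(tr), [1.0])
        two = [Tracer("a", 1, 1, D_ecs=8.0), Tracer("b", 1, 1, D_ecs=2.0)]
        np.testing.assert_allclose(
            relative_penetration(two, t=600.0), relative_penetration(two, t=7200.0), rtol=1e-9
        )

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            relative_penetration([])


class TestAlphaAdjustment:
    def test_alpha_rescales_amplitude_not_shape(self):
        prof = halfspace_profile(TransportParams(D=2.0), 100.0, np.linspace(0, 100, 20))
        a = alpha_adjusted_uptake(prof, 0.2)
        b = alpha_adjusted_uptake(prof, 0.24)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert b.amplitude / a.amplitude == pytest.approx(1.2, rel=1e-12)
        unchanged = alpha_adjusted_uptake(prof, 1.0)
        assert unchanged.amplitude == prof.amplitude

    def test_d_eff_increase_moves_half_depth_by_sqrt(self):
        d0 = decay_distance(TransportParams(D=2.0), 100.0, 0.5)
        d1 = decay_distance(TransportParams(D=2.0 * 1.2), 100.0, 0.5)
        assert d1 / d0 == pytest.approx(np.sqrt(1.2), rel=1e-6)

    def test_alpha_out_of_range(self):
        prof = halfspace_profile(TransportParams(D=1.0), 10.0, [0.0, 1.0])
        with pytest.raises(InvalidParameterError):
            alpha_adjusted_uptake(prof, 1.5)


class TestUnitsAndTypes:
    def test_cm2_um2_round_trip_exact(self):
        for d in (1.6e-7, 5.1e-7, 0.75e-7, 0.1e-7):
            assert um2_per_s_to_cm2_per_s(cm2_per_s_to_um2_per_s(d)) == d
        assert cm2_per_s_to_um2_per_s(5.1e-7) == pytest.approx(51.0)

    def test_clearance_scales_amplitude_only(self):
        depths = np.linspace(0, 50, 10)
        base = halfspace_profile(TransportParams(D=1.0), 30.0, depths)
        dec = halfspace_profile(TransportParams(D=1.0, clearance=0.01), 30.0, depths)
        np.testing.assert_array_equal(base.intensities, dec.intensities)
        assert dec.amplitude == pytest.approx(np.exp(-0.01 * 30.0))

    def test_profile_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            SpatialProfile(distances=[1.0, 2.0], intensities=[1.0, 0.5])
        with pytest.raises(InvalidParameterError):
            SpatialProfile(distances=[0.0, 0.0], intensities=[1.0, 0.5])
        with pytest.raises(InvalidParameterError):
            Tracer("x", 1, 1, D_free=1.0, D_ecs=2.0)
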