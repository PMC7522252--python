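"""Elongation, penetration resistance and the direction rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizosim.growth import (GRAVITY, DirectionDegeneracyError, GrowthTraits,
                             AxisSpec, direction_update, elongation_rate,
                             penetration_resistance, resistance_field,
                             resistance_gradient_at, rotate, sample_deviation)
from rhizosim.soil import SoilGrid, VanGenuchtenSoil, hydrostatic_init


class TestPenetrationResistance:
    @pytest.mark.parametrize("rho_b", [1.2, 1.4])
    def test_against_scalar_formula(self, rho_b):
        # |psi| Se = 1 makes the log term vanish
        expected = math.exp(0.35 * math.log10(1.0) + 0.93 * rho_b + 1.26)
        assert penetration_resistance(1.0, 1.0, rho_b) == pytest.approx(expected)

    def test_frozen_reference_values(self):
        assert penetration_resistance(1.0, 1.0, 1.2) == pytest.approx(10.76, abs=0.01)
        assert penetration_resistance(1.0, 1.0, 1.4) == pytest.approx(12.96, abs=0.01)

    def test_clamp_keeps_saturated_value_finite(self):
        r = penetration_resistance(0.0, 0.0, 1.2)
        assert np.isfinite(r) and r > 0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e4),
           st.floats(min_value=1e-3, max_value=1e4),
           st.floats(min_value=1.0, max_value=1.8))
    def test_monotone_in_suction_and_density(self, p1, p2, rho):
        lo, hi = min(p1, p2), max(p1, p2)
        assert penetration_resistance(lo, 1.0, rho) <= penetration_resistance(
            hi, 1.0, rho) + 1e-12
        assert penetration_resistance(lo, 1.0, rho) < penetration_resistance(
            lo, 1.0, rho + 0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            penetration_resistance(1.0, 1.5, 1.2)
        with pytest.raises(ValueError):
            penetration_resistance(1.0, 0.5, -1.0)


class TestElongation:
    def test_limits(self):
        assert elongation_rate(1.3, 0.0, -10.0) == 1.3
        psi = -200.0
        assert elongation_rate(1.3, 4000 + 2.33 * abs(psi), psi) == 0.0

    def test_half_inhibition(self):
        assert elongation_rate(1.0, 2000.0, 0.0) == pytest.approx(0.5)

    def test_clamped_not_negative(self):
        assert elongation_rate(1.0, 1e6, 0.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=3000),
           st.floats(min_value=0, max_value=3000))
    def test_strictly_decreasing_in_resistance(self, r1, r2):
        lo, hi = min(r1, r2), max(r1, r2)
        e_lo, e_hi = (elongation_rate(1.0, r, -50.0) for r in (lo, hi))
        assert e_lo >= e_hi
        if hi - lo > 1e-9:
            assert e_lo > e_hi


class TestDirection:
    def test_alignment_fixed_point(self):
        d = direction_update(GRAVITY, GRAVITY, None, 1.0, 0.0, 0.0)
        assert np.allclose(d, GRAVITY)

    def test_inertia_only(self):
        d0 = np.array([0.6, -0.8])
        assert np.allclose(direction_update(d0, GRAVITY, None, 0.0, 0.0, 0.0),
                           d0)

    def test_hand_computed_mix(self):
        d = direction_update(np.array([1.0, 0.0]), GRAVITY, None, 0.1, 0.0, 0.0)
        expected = np.array([1.0, -0.1]) / np.linalg.norm([1.0, -0.1])
        assert np.allclose(d, expected, atol=1e-12)
        assert d == pytest.approx(np.array([0.99504, -0.09950]), abs=1e-5)

    def test_resistance_steers_downhill(self):
        grad = np.array([10.0, 0.0])  # resistance grows towards +x
        d = direction_update(np.array([0.0, -1.0]), GRAVITY, grad, 0.0, 0.5, 0.0)
        assert d[0] < 0  # steered towards -x

    def test_degenerate_sum_raises(self):
        with pytest.raises(DirectionDegeneracyError):
            direction_update(np.array([0.0, 1.0]), GRAVITY, None, 1.0, 0.0, 0.0)

    def test_rotation_convention(self):
        assert np.allclose(rotate([1, 0], 90.0), [0, 1], atol=1e-12)

    def test_vertical_convergence_is_monotone(self):
        """With only geotropism active the tip angle to gravity shrinks."""
        d = np.array([0.94, -0.342])
        prev = np.arccos(np.clip(d @ GRAVITY, -1, 1))
        for _ in range(50):
            d = direction_update(d, GRAVITY, None, 0.15, 0.0, 0.0)
            ang = np.arccos(np.clip(d @ GRAVITY, -1, 1))
            assert ang <= prev + 1e-12
            prev = ang
        assert prev < 0.02


class TestDeviation:
    def test_degenerate_interval(self):
        assert sample_deviation(0.0, np.random.default_rng(0)) == 0.0

    def test_bounds_and_mean(self):
        rng = np.random.default_rng(42)
        samples = np.array([sample_deviation(35.0, rng) for _ in range(10000)])
        assert samples.min() >= -35.0 and samples.max() <= 35.0
        assert abs(samples.mean()) < 1.5

    def test_seeded_reproducibility(self):
        s1 = [sample_deviation(35.0, np.random.default_rng(7)) for _ in range(10)]
        s2 = [sample_deviation(35.0, np.random.default_rng(7)) for _ in range(10)]
        assert s1 == s2


class TestResistanceGradient:
    def grid_state(self):
        grid = SoilGrid(4, 4, 8, 8, 0.2)
        soil = VanGenuchtenSoil()
        return grid, soil, hydrostatic_init(grid, soil)

    def test_uniform_field_has_zero_gradient(self):
        grid, _, _ = self.grid_state()
        R = np.full(grid.n_elems, 12.0)
        assert np.allclose(resistance_gradient_at((2.0, 2.0), grid, R), 0.0)

    def test_manufactured_linear_field(self):
        grid, _, _ = self.grid_state()
        R = 3.0 * grid.elem_cx + 1.5 * grid.elem_cz
        g = resistance_gradient_at((2.0, 2.0), grid, R)
        assert g == pytest.approx([3.0, 1.5], rel=1e-9)

    def test_interface_gradient_points_to_stiff_side(self):
        grid, _, _ = self.grid_state()
        R = np.where(grid.elem_cx > 2.0, 40.0, 10.0)  # stiff on the right
        g = resistance_gradient_at((1.8, 2.0), grid, R)
        assert g[0] > 0

    def test_outside_domain_rejected(self):
        grid, _, _ = self.grid_state()
        with pytest.raises(ValueError):
            resistance_gradient_at((9.0, 2.0), grid, np.zeros(grid.n_elems))

    def test_field_reflects_material_density(self):
        grid, soil, state = self.grid_state()
        mat = np.zeros(grid.n_elems, dtype=int)
        mat[grid.elem_cx > 2.0] = 1
        from dataclasses import replace
        soils = [soil, replace(soil, rho_b=1.4)]
        R = resistance_field(grid, state, soils, mat)
        # at equal height (same water state) the denser material resists more
        Rg = R.reshape(grid.nz, grid.nx)
        mg = mat.reshape(grid.nz, grid.nx)
        for k in range(grid.nz):
            assert Rg[k][mg[k] == 1].min() > Rg[k][mg[k] == 0].max()


class TestTraits:
    def test_elongation_table_interpolation(self):
        t = GrowthTraits()
        assert t.elongation_max(1, 0.0) == 2.0
        assert t.elongation_max(1, 3.5) == 0.5
        assert t.elongation_max(1, 10.0) == 0.5   # clamped
        assert t.elongation_max(1, 1.75) == pytest.approx(1.25)
        assert t.elongation_max(2, 5.0) == 0.5

    def test_validation(self):
        with pytest.raises(ValueError):
            GrowthTraits(delta=95.0)
        with pytest.raises(ValueError):
            GrowthTraits(branch_spacing=0.0)
        with pytest.raises(ValueError):
            GrowthTraits(w_g=-0.1)

    def test_axis_direction_convention(self):
        assert np.allclose(AxisSpec(0.0, 0.0).direction, [0, -1])
        d = AxisSpec(0.0, 90.0).direction
        assert np.allclose(d, [1, 0], atol=1e-12)
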