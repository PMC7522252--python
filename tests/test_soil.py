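"""Van Genuchten closures and the Richards step."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizosim.soil import (RichardsConvergenceError, SoilGrid,
                           VanGenuchtenSoil, effective_saturation,
                           hydrostatic_init, k_of_h, richards_step,
                           theta_of_h, water_capacity)

SOIL = VanGenuchtenSoil()  # agar-substrate defaults


def vg_theta_reference(h, s):
    """Independent scalar evaluation of the retention closed form."""
    if h >= 0:
        return s.theta_s
    return s.theta_r + (s.theta_s - s.theta_r) * (
        1.0 + (s.alpha * abs(h)) ** s.n) ** (-s.m)


def vg_k_reference(h, s):
    """Independent scalar evaluation of the Mualem conductivity form
    K = Ks {1 - (a|h|)^(n-1) [1+(a|h|)^n]^(-m)}^2 [1+(a|h|)^n]^(-l m)."""
    if h >= 0:
        return s.K_s
    ah = s.alpha * abs(h)
    bracket = 1.0 + ah ** s.n
    return (s.K_s * (1.0 - ah ** (s.n - 1.0) * bracket ** (-s.m)) ** 2
            * bracket ** (-s.l_pore * s.m))


class TestRetention:
    def test_saturated_values_match_parameter_table(self):
        assert theta_of_h(0.0, SOIL) == pytest.approx(0.41, abs=1e-12)
        assert k_of_h(0.0, SOIL) == pytest.approx(10.24, abs=1e-12)

    def test_dry_limits(self):
        assert theta_of_h(-1e6, SOIL) == pytest.approx(0.06, abs=1e-3)
        assert k_of_h(-1e6, SOIL) < 1e-6 * SOIL.K_s

    @pytest.mark.parametrize("h", [-1.0 / 0.03, -5.0, -50.0, -300.0])
    def test_against_independent_closed_form(self, h):
        assert theta_of_h(h, SOIL) == pytest.approx(vg_theta_reference(h, SOIL),
                                                    rel=1e-12)
        assert k_of_h(h, SOIL) == pytest.approx(vg_k_reference(h, SOIL),
                                                rel=1e-10)

    def test_inflection_point_value(self):
        # at h = -1/alpha the retention reduces to theta_r + dtheta * 2^-m
        expected = 0.06 + 0.35 * 2 ** (-(1 - 1 / 2.51))
        assert theta_of_h(-1 / 0.03, SOIL) == pytest.approx(expected, rel=1e-12)

    def test_effective_saturation_endpoints(self):
        assert effective_saturation(SOIL.theta_s, SOIL) == 1.0
        assert effective_saturation(SOIL.theta_r, SOIL) == 0.0
        mid = 0.5 * (SOIL.theta_r + SOIL.theta_s)
        assert effective_saturation(mid, SOIL) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            effective_saturation(SOIL.theta_s + 0.05, SOIL)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-1e5, max_value=50),
           st.floats(min_value=-1e5, max_value=50))
    def test_theta_and_k_monotone_in_h(self, h1, h2):
        lo, hi = min(h1, h2), max(h1, h2)
        assert theta_of_h(lo, SOIL) <= theta_of_h(hi, SOIL) + 1e-15
        assert k_of_h(lo, SOIL) <= k_of_h(hi, SOIL) + 1e-15

    def test_capacity_is_derivative(self):
        h = -37.0
        eps = 1e-6
        fd = (theta_of_h(h + eps, SOIL) - theta_of_h(h - eps, SOIL)) / (2 * eps)
        assert water_capacity(h, SOIL) == pytest.approx(fd, rel=1e-5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            VanGenuchtenSoil(theta_r=0.5, theta_s=0.4)
        with pytest.raises(ValueError):
            VanGenuchtenSoil(n=0.9)
        assert VanGenuchtenSoil(n=2.51).m == pytest.approx(1 - 1 / 2.51)


class TestRichards:
    def test_hydrostatic_is_fixed_point(self):
        grid = SoilGrid(10, 10, 12, 12, 0.2)
        state = hydrostatic_init(grid, SOIL)
        zero = np.zeros(grid.n_elems)
        for _ in range(10):
            state2 = richards_step(grid, state, SOIL, zero, zero, 0.05)
            assert np.max(np.abs(state2.h - state.h)) < 1e-6
            state = state2

    def test_hydrostatic_profile(self):
        grid = SoilGrid(4, 8, 4, 8, 0.1)
        st_ = hydrostatic_init(grid, SOIL, water_table_z=0.0)
        assert np.allclose(st_.h + grid.node_z, 0.0)
        assert st_.h[grid.node_z == 0].max() == 0.0

    def test_uniform_sink_mass_conservation(self):
        grid = SoilGrid(5, 5, 10, 10, 0.2)
        state = hydrostatic_init(grid, SOIL)
        sink = np.full(grid.n_elems, 0.02)
        new = richards_step(grid, state, SOIL, np.zeros(grid.n_elems),
                            sink, 0.1)
        dstorage = np.sum((new.theta - state.theta) * grid.node_volumes)
        expected = -np.sum(sink * grid.elem_volume) * 0.1
        assert dstorage == pytest.approx(expected, rel=1e-8)
        assert abs(new.mass_balance_error) < 1e-8

    def test_random_sink_mass_conservation(self):
        rng = np.random.default_rng(0)
        grid = SoilGrid(5, 5, 8, 8, 0.2)
        state = hydrostatic_init(grid, SOIL)
        sink = rng.uniform(0, 0.05, grid.n_elems)
        new = richards_step(grid, state, SOIL, np.zeros(grid.n_elems),
                            sink, 0.05)
        dstorage = np.sum((new.theta - state.theta) * grid.node_volumes)
        assert dstorage == pytest.approx(-np.sum(sink * grid.elem_volume) * 0.05,
                                         rel=1e-8)

    def test_dirichlet_bottom_supplies_water(self):
        grid = SoilGrid(5, 5, 8, 8, 0.2)
        state = hydrostatic_init(grid, SOIL)
        sink = np.full(grid.n_elems, 0.05)
        new = richards_step(grid, state, SOIL, np.zeros(grid.n_elems),
                            sink, 0.2, bottom_head=0.0)
        assert new.boundary_flux > 0  # water enters through the held bottom
        assert np.allclose(new.h[:grid.nx + 1], 0.0)

    def test_declared_failure_contract(self):
        grid = SoilGrid(5, 5, 8, 8, 0.2)
        state = hydrostatic_init(grid, SOIL)
        sink = np.full(grid.n_elems, 5.0)  # unsustainably sharp drawdown
        with pytest.raises(RichardsConvergenceError) as exc:
            richards_step(grid, state, SOIL, np.zeros(grid.n_elems), sink,
                          5.0, max_iter=2, min_substep_frac=0.5)
        assert exc.value.residual > 0

    def test_grid_refinement_converges(self):
        """Halving the element size changes the 1-step field by less."""
        def run(n):
            grid = SoilGrid(4, 4, n, n, 0.2)
            state = hydrostatic_init(grid, SOIL)
            sink = np.zeros(grid.n_elems)
            # a localised sink block in the domain centre
            cx = (np.abs(grid.elem_cx - 2) < 1) & (np.abs(grid.elem_cz - 2) < 1)
            sink[cx] = 0.2
            out = richards_step(grid, state, SOIL, np.zeros(grid.n_elems),
                                sink, 0.5)
            return grid, out

        probes_x, probes_z = np.meshgrid(np.linspace(0.5, 3.5, 7),
                                         np.linspace(0.5, 3.5, 7))
        fields = {}
        for n in (8, 16, 32):
            grid, out = run(n)
            fields[n] = grid.interp_nodal(out.h, probes_x.ravel(),
                                          probes_z.ravel())
        d1 = np.max(np.abs(fields[16] - fields[8]))
        d2 = np.max(np.abs(fields[32] - fields[16]))
        assert d2 < d1

    def test_invalid_dt(self):
        grid = SoilGrid(2, 2, 2, 2, 0.1)
        state = hydrostatic_init(grid, SOIL)
        with pytest.raises(ValueError):
            richards_step(grid, state, SOIL, np.zeros(grid.n_elems),
                          np.zeros(grid.n_elems), -0.1)
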