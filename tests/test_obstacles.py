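"""Obstacle geometry, the contact/recovery phase machine and sliding."""

import numpy as np
import pytest

from rhizosim.obstacles import (ContactState, Obstacle, StateError,
                                clamp_to_obstacle, distance_to_obstacle,
                                path_blocked, rasterize_obstacles,
                                slide_direction, update_contact_state,
                                w_o_weight)
from rhizosim.soil import SoilGrid

GRAV = np.array([0.0, -1.0])


class TestRasterize:
    def test_axis_aligned_centroid_rule(self):
        grid = SoilGrid(4, 4, 8, 8, 0.1)  # centroids at 0.25 + 0.5k
        obs = Obstacle(center=(1.0, 1.0), length=1.0, width=1.0, eta=0.0)
        mat = rasterize_obstacles([obs], grid)
        assert (mat == 1).sum() == 4
        assert mat[grid.locate(1.0, 1.0)] == 1

    def test_empty_list_all_substrate(self):
        grid = SoilGrid(4, 4, 4, 4, 0.1)
        assert np.all(rasterize_obstacles([], grid) == 0)

    def test_rotated_rectangle_matches_pointwise_oracle(self):
        grid = SoilGrid(4.8, 6.8, 24, 34, 0.08)
        obs = Obstacle(center=(2.4, 3.4), length=2.0, width=0.3, eta=45.0)
        mat = rasterize_obstacles([obs], grid)
        # independent oracle: rotate centroids into the obstacle frame
        c, s = np.cos(np.radians(45)), np.sin(np.radians(45))
        dx = grid.elem_cx - 2.4
        dz = grid.elem_cz - 3.4
        u = c * dx + s * dz
        v = -s * dx + c * dz
        inside = (np.abs(u) <= 1.0) & (np.abs(v) <= 0.15)
        assert np.array_equal(mat == 1, inside)

    def test_obstacle_outside_domain_rejected(self):
        grid = SoilGrid(2, 2, 4, 4, 0.1)
        with pytest.raises(ValueError):
            rasterize_obstacles([Obstacle(center=(1.9, 1.0), length=1.0,
                                          width=0.2)], grid)


class TestDistance:
    OBS = Obstacle(center=(2.0, 2.0), length=2.0, width=0.4, eta=0.0)

    def test_point_on_edge(self):
        d, _, _ = distance_to_obstacle((2.0, 2.2), [self.OBS])
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_normal_distance(self):
        d, obs, tangent = distance_to_obstacle((2.0, 3.2), [self.OBS])
        assert d == pytest.approx(1.0, abs=1e-12)
        assert obs is self.OBS
        assert abs(tangent[1]) < 1e-12  # nearest edge is horizontal

    def test_tangent_sense_follows_direction(self):
        _, _, t1 = distance_to_obstacle((2.0, 2.3), [self.OBS],
                                        direction=np.array([1.0, 0.0]))
        _, _, t2 = distance_to_obstacle((2.0, 2.3), [self.OBS],
                                        direction=np.array([-1.0, 0.0]))
        assert t1[0] > 0 > t2[0]

    def test_against_sampled_periphery_oracle(self):
        obs = Obstacle(center=(2.0, 2.0), length=2.0, width=0.4, eta=30.0)
        corners = np.asarray(obs.polygon.exterior.coords)
        frac = np.linspace(0.0, 1.0, 20001)[:, None]
        samples = np.vstack([a + frac * (b - a)
                             for a, b in zip(corners[:-1], corners[1:])])
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(0, 4, size=2)
            d, _, _ = distance_to_obstacle(p, [obs])
            oracle = np.min(np.linalg.norm(samples - p, axis=1))
            assert d == pytest.approx(oracle, abs=1e-6)

    def test_empty_obstacle_list(self):
        d, obs, tangent = distance_to_obstacle((0.0, 0.0), [])
        assert np.isinf(d) and obs is None


class TestPhaseMachine:
    def make(self):
        return ContactState(w_oi=5.0, kappa=2.0)

    def test_episode_times_and_kappa(self):
        st = self.make()
        d = np.array([1.0, 0.0])
        assert update_contact_state(st, True, 1.0, d) == "contact_start"
        update_contact_state(st, True, 1.2, d)
        assert update_contact_state(st, False, 1.5, d) == "recovery_start"
        assert st.t0 == 1.0 and st.t1 == 1.5
        assert st.t2 == pytest.approx(2.5)
        assert (st.t2 - st.t1) == pytest.approx(st.kappa * (st.t1 - st.t0))

    def test_never_in_contact_stays_inert(self):
        st = self.make()
        for t in np.arange(0, 2, 0.1):
            assert update_contact_state(st, False, t, GRAV) is None
        assert st.phase == "free" and w_o_weight(st, 2.0) == 0.0

    def test_recontact_cancels_recovery(self):
        st = self.make()
        d = np.array([1.0, 0.0])
        update_contact_state(st, True, 1.0, d)
        update_contact_state(st, False, 1.5, d)
        assert st.phase == "recovery"
        assert update_contact_state(st, True, 1.8, d) == "contact_start"
        assert st.phase == "contact" and st.t0 == 1.8

    def test_recovery_completes(self):
        st = self.make()
        d = np.array([1.0, 0.0])
        update_contact_state(st, True, 1.0, d)
        update_contact_state(st, False, 1.5, d)
        assert update_contact_state(st, False, 2.49, d) is None
        assert update_contact_state(st, False, 2.5, d) == "recovered"
        assert st.phase == "free"

    def test_time_regression_rejected(self):
        st = self.make()
        update_contact_state(st, True, 1.0, GRAV)
        with pytest.raises(StateError):
            update_contact_state(st, True, 0.5, GRAV)

    def test_mean_contact_direction(self):
        st = self.make()
        update_contact_state(st, True, 1.0, np.array([1.0, 0.0]))
        update_contact_state(st, True, 1.1, np.array([0.0, 1.0]))
        update_contact_state(st, False, 1.2, np.array([0.0, 1.0]))
        expected = np.array([1.0, 1.0]) / np.sqrt(2)
        assert np.allclose(st.mean_dir, expected)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ContactState(w_oi=1.0)
        with pytest.raises(ValueError):
            ContactState(kappa=0.0)


class TestWoSchedule:
    def recovery_state(self):
        st = ContactState(w_oi=5.0, kappa=2.0)
        update_contact_state(st, True, 1.0, np.array([1.0, 0.0]))
        update_contact_state(st, False, 1.5, np.array([1.0, 0.0]))
        return st  # t1=1.5, t2=2.5

    def test_contact_weight_is_one(self):
        st = ContactState(w_oi=5.0, kappa=2.0)
        update_contact_state(st, True, 1.0, np.array([1.0, 0.0]))
        assert w_o_weight(st, 1.2) == 1.0

    def test_linear_decay_endpoints(self):
        st = self.recovery_state()
        assert w_o_weight(st, 1.5) == pytest.approx(5.0)
        assert w_o_weight(st, 2.0) == pytest.approx(2.5)
        assert w_o_weight(st, 2.5) == 0.0
        assert w_o_weight(st, 3.0) == 0.0

    def test_non_increasing_over_recovery(self):
        st = self.recovery_state()
        ts = np.linspace(1.5, 2.5, 101)
        ws = [w_o_weight(st, t) for t in ts]
        assert all(a >= b for a, b in zip(ws, ws[1:]))
        assert max(ws) <= max(1.0, st.w_oi)

    def test_history_vector_uses_mean_once(self):
        st = self.recovery_state()
        d_old = np.array([0.0, -1.0])
        first = st.history_vector(d_old)
        assert np.allclose(first, st.mean_dir)
        second = st.history_vector(d_old)
        assert np.allclose(second, d_old)

    def test_evaluation_before_contact_start_rejected(self):
        st = self.recovery_state()
        with pytest.raises(StateError):
            w_o_weight(st, 0.5)


class TestSliding:
    def test_slide_along_inclined_edge(self):
        obs = Obstacle(center=(2.0, 2.0), length=2.0, width=0.2, eta=45.0)
        p = np.array(obs.polygon.exterior.coords[0])  # a corner on the edge
        tangent = np.array([np.cos(np.radians(45)), np.sin(np.radians(45))])
        d = slide_direction(np.array([0.0, -1.0]), tangent, GRAV)
        beta = np.degrees(np.arctan2(abs(d[1]), abs(d[0])))
        assert beta == pytest.approx(45.0)

    def test_horizontal_edge_gives_horizontal_slide(self):
        tangent = np.array([1.0, 0.0])
        d = slide_direction(np.array([0.3, -0.95]), tangent, GRAV)
        assert abs(d[1]) < 1e-12 and abs(abs(d[0]) - 1) < 1e-12

    def test_normal_approach_falls_back_to_gravity_sense(self):
        tangent = np.array([0.0, 1.0])  # vertical edge
        d = slide_direction(np.array([1.0, 0.0]), tangent, GRAV)
        assert d[1] < 0

    def test_unblocked_path_is_noop(self):
        obs = Obstacle(center=(2.0, 2.0), length=2.0, width=0.2, eta=0.0)
        assert not path_blocked((2.0, 3.0), (1.0, 0.0), 0.5, obs)
        assert path_blocked((2.0, 2.2), (0.0, -1.0), 0.5, obs)

    def test_clamp_stops_before_entry(self):
        obs = Obstacle(center=(2.0, 2.0), length=2.0, width=0.4, eta=0.0)
        s = clamp_to_obstacle((2.0, 2.5), (0.0, -1.0), 1.0, obs, margin=0.05)
        assert s == pytest.approx(0.25, abs=1e-9)


class TestTrajectoryInvariants:
    def test_no_endpoint_inside_obstacle(self, obstacle_traj):
        polys = [o.polygon.buffer(-1e-9) for o in obstacle_traj.config.obstacles]
        from shapely.geometry import Point
        for root in obstacle_traj.system.roots.values():
            for p in root.points:
                assert not any(poly.contains(Point(p)) for poly in polys)

    def test_episode_ratio_is_kappa_exactly(self, obstacle_traj):
        for ep in obstacle_traj.episodes:
            ratio = (ep["t2"] - ep["t1"]) / (ep["t1"] - ep["t0"])
            assert ratio == pytest.approx(obstacle_traj.config.kappa, rel=1e-12)

    def test_contact_plateau_at_inclination(self, obstacle_traj):
        log = obstacle_traj.tip_log
        ax = log[(log.root_id == 1) & (log.phase == "contact")]
        assert len(ax) > 5
        # the sliding portion of the contact window sits on the 45-deg edge
        mid = ax.iloc[len(ax) // 3: 2 * len(ax) // 3]
        assert np.median(np.abs(mid.beta - 45.0)) < 5.0

    def test_angle_returns_to_vertical_after_recovery(self, obstacle_traj):
        ep = obstacle_traj.episodes[0]
        log = obstacle_traj.tip_log
        ax = log[log.root_id == 1]
        after = ax[ax.t > ep["t2"]]
        assert len(after) > 0
        assert np.all(np.abs(after.beta - 90.0) < 5.0)
        # monotone return towards vertical during recovery (allowing the
        # sub-0.05-degree wiggle the interpolated resistance field induces)
        rec = ax[(ax.t > ep["t1"] + 0.1) & (ax.t < ep["t2"])]
        dev = np.abs(rec.beta.to_numpy() - 90.0)
        assert np.all(np.diff(dev) < 0.05)
        assert dev[-1] < dev[0]
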