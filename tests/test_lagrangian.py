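"""Particle kinematics: interpolation, advection oracle, DVM, boundaries."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

import larvadrift as ld
from larvadrift.exceptions import ConfigurationError
from larvadrift.lagrangian import (FieldSampler, dvm_target_depth,
                                   handle_boundary, vertical_update)

from conftest import make_analytic_archive


@pytest.fixture(scope="module")
def flat_grid():
    # deep flat bathymetry so vertical structure is out of the way
    x_edges = np.arange(0.0, 61.0, 3.0)
    y_edges = np.arange(0.0, 101.0, 5.0)
    z_edges = np.arange(0.0, 201.0, 25.0)
    bathy = np.full((y_edges.size - 1, x_edges.size - 1), 200.0)
    return ld.ShelfGrid(x_edges, y_edges, z_edges, bathy)


class TestInterpolation:
    def test_exact_at_nodes_and_snapshots(self, coarse_archive):
        arc, _ = coarse_archive
        g = arc.grid
        it, iz, iy, ix = 3, 2, 4, 5
        vals = ld.lagrangian.interpolate_fields(
            arc, [[g.x_centers[ix], g.y_centers[iy], g.z_centers[iz]]],
            arc.snapshot_times[it])
        expect = [getattr(arc, n)[it, iz, iy, ix] for n in ("u", "v", "w", "T", "S")]
        np.testing.assert_allclose([v[0] for v in vals], expect, rtol=1e-6)

    def test_constant_field_identity(self, flat_grid):
        arc = make_analytic_archive(lambda x, y: 0.1, lambda x, y: 0.0, flat_grid)
        u, v, w, T, S = ld.lagrangian.interpolate_fields(
            arc, [[13.7, 42.1, 77.0]], 5.3)
        assert np.isclose(u[0], 0.1, atol=1e-7)
        assert np.isclose(T[0], 15.0, atol=1e-5)

    def test_linear_in_time_between_snapshots(self, flat_grid):
        arc = make_analytic_archive(lambda x, y: 0.0, lambda x, y: 0.0,
                                    flat_grid, duration_hours=8.0)
        arc.u[1] = 0.2  # snapshot at t=4h
        sampler = FieldSampler(arc)
        (u,) = sampler.sample(np.array([10.0]), np.array([50.0]),
                              np.array([50.0]), 2.0, ("u",))
        assert np.isclose(u[0], 0.1, atol=1e-7)

    def test_matches_scipy_regular_grid_interpolator(self, coarse_archive):
        """Independent oracle: scipy's linear interpolator on (t,z,y,x)."""
        arc, _ = coarse_archive
        g = arc.grid
        rng = np.random.default_rng(7)
        n = 200
        x = rng.uniform(g.x_centers[0], g.x_centers[-1], n)
        y = rng.uniform(g.y_centers[0], g.y_centers[-1], n)
        z = rng.uniform(g.z_centers[0], g.z_centers[-1], n)
        t = rng.uniform(arc.snapshot_times[0], arc.snapshot_times[-1])
        sampler = FieldSampler(arc)
        for name in ("u", "v", "T"):
            rgi = RegularGridInterpolator(
                (arc.snapshot_times, g.z_centers, g.y_centers, g.x_centers),
                getattr(arc, name).astype(float))
            mine = sampler.sample(x, y, z, t, (name,))[0]
            ref = rgi(np.column_stack([np.full(n, t), z, y, x]))
            np.testing.assert_allclose(mine, ref, atol=1e-6)


class TestAdvection:
    def test_zero_flow_is_fixed_point(self, flat_grid):
        arc = make_analytic_archive(lambda x, y: 0.0, lambda x, y: 0.0, flat_grid)
        X = np.array([[20.0, 50.0, 30.0]])
        X2 = ld.lagrangian.step_position(X, 10.0, arc, ld.TrackerConfig())
        np.testing.assert_array_equal(X2, X)

    def test_uniform_flow_displacement(self, flat_grid):
        """u = 0.1 m/s over a 300 s step displaces x by exactly 30 m."""
        arc = make_analytic_archive(lambda x, y: 0.1, lambda x, y: 0.0, flat_grid)
        X = np.array([[20.0, 50.0, 30.0]])
        X2 = ld.lagrangian.step_position(X, 10.0, arc, ld.TrackerConfig())
        assert np.isclose(X2[0, 0] - X[0, 0], 0.030, atol=1e-9)
        assert X2[0, 1] == X[0, 1]

    def test_solid_body_rotation_against_tiny_step_euler(self, flat_grid):
        """1000 Heun steps in a rotating field conserve radius to 1e-3 and
        match a 1-second Euler integration to 1e-2 relative."""
        x0, y0 = 30.0, 50.0
        omega = 2 * np.pi / (48 * 3600.0)  # rad/s, 48-h rotation period
        arc = make_analytic_archive(
            lambda x, y: -omega * (y - y0) * 1e3,  # m/s from km offsets
            lambda x, y: omega * (x - x0) * 1e3,
            flat_grid, duration_hours=100.0)
        cfg = ld.TrackerConfig(dt_seconds=300.0)
        X = np.array([[x0 + 10.0, y0, 30.0]])
        r0 = 10.0
        t = 0.0
        for _ in range(1000):
            X = ld.lagrangian.step_position(X, t, arc, cfg)
            t += cfg.dt_hours
        r1 = np.hypot(X[0, 0] - x0, X[0, 1] - y0)
        assert abs(r1 - r0) / r0 < 1e-3
        # brute-force 1 s Euler oracle
        xe, ye = x0 + 10.0, y0
        for _ in range(1000 * 300):
            u = -omega * (ye - y0)
            v = omega * (xe - x0)
            xe += u
            ye += v
        err = np.hypot(X[0, 0] - xe, X[0, 1] - ye) / r0
        assert err < 1e-2

    def test_run_deterministic_and_replicate_independent(self, coarse_archive):
        """Same physics seed gives bitwise-equal trajectories regardless of
        the mortality replicate seeds."""
        arc, ests = coarse_archive
        plan = ld.build_release_plan(ests, "2006-02-01", "2006-02-05",
                                     ld.ReleaseConfig(larvae_per_night=20),
                                     seed=3)
        kw = dict(tracker_cfg=ld.TrackerConfig(seed=5),
                  bio_cfg=ld.BioConfig(mortality_on=True), mode="base",
                  record=True)
        a = ld.run_tracker(arc, plan, replicate_seeds=(1,), **kw)
        b = ld.run_tracker(arc, plan, replicate_seeds=(2,), **kw)
        np.testing.assert_array_equal(a.traj_x, b.traj_x)
        np.testing.assert_array_equal(a.traj_z, b.traj_z)


class TestDVM:
    def test_day_target_capped_at_60m_when_deeper(self):
        assert dvm_target_depth(12.0, 80.0) == 60.0

    def test_day_target_is_bottom_layer_when_shallow(self):
        cfg = ld.DVMConfig()
        assert dvm_target_depth(12.0, 40.0) == 40.0 - cfg.bottom_clearance_m

    def test_night_target_is_surface(self):
        cfg = ld.DVMConfig()
        t = dvm_target_depth(23.0, np.array([40.0, 100.0]), cfg)
        np.testing.assert_array_equal(t, cfg.surface_depth_m)

    def test_transit_ramps_between_levels(self):
        cfg = ld.DVMConfig()
        dusk_mid = dvm_target_depth(21.0, 100.0, cfg)
        assert cfg.surface_depth_m < dusk_mid < 60.0
        dawn_mid = dvm_target_depth(5.0, 100.0, cfg)
        assert cfg.surface_depth_m < dawn_mid < 60.0

    def test_descent_kinematics(self):
        """From the surface at 06:00, 0.01 m/s swimming reaches 60 m in 6000 s."""
        cfg = ld.TrackerConfig(w_turb_sigma=0.0)
        z = np.array([0.0])
        for _ in range(20):  # 20 steps x 300 s = 6000 s
            z = vertical_update(z, 0.0, np.array([60.0]), np.array([100.0]),
                                cfg, np.zeros(1))
        np.testing.assert_allclose(z, 60.0, atol=1e-9)

    def test_at_target_no_turbulence_is_equilibrium(self):
        cfg = ld.TrackerConfig(w_turb_sigma=0.0)
        z = np.array([60.0])
        z2 = vertical_update(z, 0.0, np.array([60.0]), np.array([100.0]),
                             cfg, np.zeros(1))
        np.testing.assert_array_equal(z2, z)

    def test_reflecting_random_walk_stays_bounded_zero_mean(self):
        """10^4 turbulent particles stay in [0, bottom]; mean drift ~ 0."""
        cfg = ld.TrackerConfig(w_turb_sigma=5e-3, dvm=False)
        rng = np.random.default_rng(11)
        n = 10_000
        z = np.full(n, 50.0)
        bottom = np.full(n, 100.0)
        for _ in range(500):
            z = vertical_update(z, 0.0, z, bottom, cfg, rng.standard_normal(n),
                                dvm_on=False)
        assert z.min() >= 0.0 and z.max() <= 100.0
        # mean displacement small relative to the walk scale
        assert abs(z.mean() - 50.0) < 3.0


class TestBoundaries:
    def test_open_policy_flags_exits(self, flat_grid):
        x = np.array([65.0, 30.0, 30.0])
        y = np.array([50.0, -5.0, 50.0])
        _, _, left = handle_boundary(x, y, flat_grid, "open")
        np.testing.assert_array_equal(left, [True, True, False])

    def test_coast_policy_repositions_onshore_overshoot(self, flat_grid):
        x = np.array([-0.5, 10.0])
        y = np.array([50.0, 50.0])
        x2, _, left = handle_boundary(x, y, flat_grid, "coast")
        assert x2[0] > 0.0 and x2[1] == 10.0
        assert not left.any()

    def test_interior_particles_unchanged(self, flat_grid):
        x = np.array([10.0, 20.0])
        y = np.array([40.0, 60.0])
        x2, y2, left = handle_boundary(x, y, flat_grid, "open")
        np.testing.assert_array_equal(x2, x)
        np.testing.assert_array_equal(y2, y)
        assert not left.any()

    def test_unknown_policy_rejected(self, flat_grid):
        with pytest.raises(ConfigurationError):
            handle_boundary(np.zeros(1), np.zeros(1), flat_grid, "bounce")
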