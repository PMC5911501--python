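"""Orifice area, rotation angle, lambda2, von Mises field, writers."""

import os

import numpy as np
import pytest

from valvefsi.contact import ContactState, check_and_close
from valvefsi.continuum import MaterialConstants
from valvefsi.errors import ConfigurationError, ValveFsiError
from valvefsi.geometry import BmhvParams, generate_bmhv
from valvefsi.postprocess import (
    TimeSeries,
    angular_velocity,
    geometric_orifice_area,
    lambda2_field,
    rotation_angle,
    von_mises_field,
    write_outputs,
)
from valvefsi.solver import State, theta_from_regions


class TestGOA:
    def test_no_leaflets_gives_full_disc_area(self):
        """BMHV measurement plane with the leaflets removed: pi R^2."""
        m = generate_bmhv(BmhvParams(mesh_size=3.0))
        theta = np.ones(m.num_cells)
        m2 = m.copy()
        m2.region_tags[:] = 1  # erase the leaflets
        R = m.metadata["params"].aorta_radius * 1e-3
        area = geometric_orifice_area(m2, theta)
        assert area == pytest.approx(np.pi * R**2, rel=0.02)

    def test_closed_valve_reports_exactly_zero(self, channel):
        theta = theta_from_regions(channel)
        theta2, cs = check_and_close(channel, theta,
                                     ContactState(threshold=1.0), d_min=0.0)
        assert cs.closed
        assert geometric_orifice_area(channel, theta2) == 0.0

    def test_open_channel_gap_length(self, channel):
        """Upright 17 mm leaflet in a 20 mm channel: 3 mm of open closure
        line (2D orifice 'area' is a transverse length)."""
        theta = theta_from_regions(channel)
        goa = geometric_orifice_area(channel, theta)
        assert goa == pytest.approx(3.0e-3, rel=0.05)

    def test_half_covered_disc(self):
        """Constructed occlusion: leaflets covering about half the orifice
        measurement plane halve the reported area."""
        m = generate_bmhv(BmhvParams(mesh_size=3.0))
        theta = np.ones(m.num_cells)
        R = m.metadata["params"].aorta_radius * 1e-3
        area = geometric_orifice_area(m, theta)
        # oracle: the unoccluded region is the central band |x| < x_h plus
        # the clearance beyond the leaflet tips |x| > x_h + chord
        p = m.metadata["params"]
        x_h, tip = p.hinge_offset * 1e-3, (p.hinge_offset + p.leaflet_chord) * 1e-3

        def band_area(a, b):  # area of the disc with a < x < b
            f = lambda x: x * np.sqrt(max(R**2 - x**2, 0)) + \
                R**2 * np.arcsin(np.clip(x / R, -1, 1))
            return f(b) - f(a)

        expected = band_area(-x_h, x_h) + 2 * band_area(tip, R)
        assert area == pytest.approx(expected, rel=0.1)

    def test_missing_closure_tag_raises(self, square8):
        with pytest.raises(ConfigurationError):
            geometric_orifice_area(square8, np.ones(square8.num_cells))


class TestRotationAngle:
    def test_closed_reference_plane_gives_zero(self, rng):
        pts = np.column_stack([rng.uniform(size=20), rng.uniform(size=20),
                               np.zeros(20)])
        a, b = np.array([0.0, -1.0, 0.0]), np.array([0.0, 1.0, 0.0])
        ang = rotation_angle(pts, a, b, closed_normal=np.array([0.0, 0.0, 1.0]))
        assert ang == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_rigid_rotation_recovered(self, rng):
        """Rotating a planar leaflet 30 degrees about its hinge reproduces
        exactly that angle."""
        pts = np.column_stack([rng.uniform(0.2, 1.0, 30),
                               rng.uniform(-0.5, 0.5, 30), np.zeros(30)])
        th = np.radians(30.0)
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        rot = pts @ R.T
        a, b = np.array([0.0, -1.0, 0.0]), np.array([0.0, 1.0, 0.0])
        ang = rotation_angle(rot, a, b, closed_normal=np.array([0.0, 0.0, 1.0]))
        assert ang == pytest.approx(30.0, abs=1e-6)

    def test_collinear_leaflet_raises(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 1.0, 0.0]))
        with pytest.raises(ValveFsiError):
            rotation_angle(pts, np.zeros(3), np.array([0, 1.0, 0]),
                           np.array([0.0, 0.0, 1.0]))

    def test_degenerate_hinge_raises(self, rng):
        pts = rng.uniform(size=(10, 3))
        with pytest.raises(ConfigurationError):
            rotation_angle(pts, np.ones(3), np.ones(3),
                           np.array([0.0, 0.0, 1.0]))

    def test_constant_angle_series_has_zero_rate(self):
        t = np.linspace(0, 1, 11)
        om = angular_velocity(t, np.full(11, 45.0))
        assert np.allclose(om, 0.0)


class TestLambda2:
    @pytest.fixture(scope="class")
    def tube(self):
        return generate_bmhv(BmhvParams(mesh_size=4.0))

    def test_rigid_rotation_gives_minus_omega_squared(self, tube):
        """U = omega x r: S = 0, so S^2+W^2 has eigenvalues
        {-w^2, -w^2, 0} and lambda2 = -|omega|^2 everywhere."""
        w = 3.0
        U = np.column_stack([
            -w * tube.vertices[:, 1], w * tube.vertices[:, 0],
            np.zeros(tube.num_vertices),
        ])
        lam2 = lambda2_field(U, tube)
        assert np.allclose(lam2, -(w**2), rtol=1e-9)

    def test_uniform_flow_is_zero(self, tube):
        U = np.tile([0.1, -0.2, 0.9], (tube.num_vertices, 1))
        assert np.abs(lambda2_field(U, tube)).max() < 1e-12

    def test_pure_strain_is_nonnegative(self, tube):
        """Irrotational straining field: S^2 has nonnegative eigenvalues,
        so no vortex is reported."""
        x = tube.vertices
        U = np.column_stack([x[:, 0], x[:, 1], -2 * x[:, 2]])  # div-free strain
        assert lambda2_field(U, tube).min() >= -1e-12

    def test_galilean_invariance(self, tube, rng):
        U = rng.normal(size=(tube.num_vertices, 3))
        shift = np.array([1.3, -0.4, 2.2])
        assert np.allclose(lambda2_field(U, tube),
                           lambda2_field(U + shift, tube), atol=1e-9)

    def test_2d_mesh_rejected(self, channel):
        with pytest.raises(ValveFsiError):
            lambda2_field(np.zeros((channel.num_vertices, 2)), channel)


class TestVonMisesField:
    def test_quiescent_uniform_pressure_is_zero(self, channel):
        st = State.zeros(channel)
        st.P[:] = 1000.0
        theta = theta_from_regions(channel)
        tv = von_mises_field(st, theta, channel, MaterialConstants())
        assert np.abs(tv).max() < 1e-9

    def test_analytic_shear_matches_sqrt2_s(self):
        """Couette-type shear: per-cell stress is 2 mu eps, von Mises is
        sqrt(2) mu gamma in every fluid cell."""
        from valvefsi.fixtures import unit_square_mesh

        mesh = unit_square_mesh(4)
        st = State.zeros(mesh)
        gamma = 10.0
        st.U[:, 0] = gamma * mesh.vertices[:, 1]
        mat = MaterialConstants(mu_f=0.5)
        tv = von_mises_field(st, np.ones(mesh.num_cells), mesh, mat)
        assert np.allclose(tv, np.sqrt(2) * 0.5 * gamma, rtol=1e-9)

    def test_log_scale_matches_linear_under_exp(self, channel):
        st = State.zeros(channel)
        st.U = 0.3 * channel.vertices[:, ::-1]
        theta = theta_from_regions(channel)
        mat = MaterialConstants()
        lin = von_mises_field(st, theta, channel, mat)
        logv = von_mises_field(st, theta, channel, mat, log_scale=True)
        pos = lin > 1e-12
        assert np.allclose(10.0**logv[pos], lin[pos], rtol=1e-9)


class TestTimeSeriesAndWriters:
    def test_strictly_increasing_time_enforced(self):
        ts = TimeSeries()
        ts.append(0.0, GOA=1.0)
        with pytest.raises(ValueError):
            ts.append(0.0, GOA=2.0)

    def test_csv_round_trip(self, tmp_path):
        ts = TimeSeries()
        for k in range(3):
            ts.append(0.1 * (k + 1), GOA=float(k), d_min=2.0 * k)
        path = str(tmp_path / "ts.csv")
        ts.to_csv(path)
        data = np.genfromtxt(path, delimiter=",", names=True)
        assert list(data.dtype.names) == ["t", "GOA", "d_min"]
        assert np.allclose(data["GOA"], [0.0, 1.0, 2.0])

    def test_three_step_trajectory_writes_vtu_pvd_csv(self, tmp_path, channel):
        theta = theta_from_regions(channel)
        traj = []
        for k in range(3):
            st = State.zeros(channel, t=0.1 * (k + 1))
            traj.append((channel, st, theta))
        ts = TimeSeries()
        for k in range(3):
            ts.append(0.1 * (k + 1), GOA=0.0)
        files = write_outputs(traj, str(tmp_path), ts)
        vtus = [f for f in files if f.endswith(".vtu")]
        assert len(vtus) == 3
        assert any(f.endswith(".pvd") for f in files)
        csv = os.path.join(str(tmp_path), "timeseries.csv")
        assert os.path.exists(csv)
        assert len(np.genfromtxt(csv, delimiter=",", names=True)) == 3

    def test_empty_trajectory_warns_and_writes_nothing(self, tmp_path):
        with pytest.warns(UserWarning):
            files = write_outputs([], str(tmp_path / "none"))
        assert files == []
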