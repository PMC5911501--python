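"""Stabilized P1-P1 ALE solver: stabilization, CFL control, linear solver,
assembly correctness (free stream, Couette, manufactured convergence),
Picard behaviour."""

import numpy as np
import pytest
import scipy.sparse as sp

from valvefsi.continuum import MaterialConstants
from valvefsi.errors import NonConvergenceError, StepRejected
from valvefsi.fixtures import (
    make_couette,
    make_taylor_green,
    make_uniform_advection,
    unit_square_mesh,
)
from valvefsi.mesh import cell_diameters, cell_volumes
from valvefsi.solver import (
    BoundaryConditions,
    SolverConfig,
    State,
    assemble_system,
    cfl_timestep,
    picard_step,
    solve_linear,
    stabilization_params,
)


def l2_velocity_error(mesh, U, exact):
    err = U - exact
    vol = cell_volumes(mesh.vertices, mesh.cells)
    w = np.zeros(mesh.num_vertices)
    np.add.at(w, mesh.cells.ravel(), np.repeat(vol / 3, 3))
    return np.sqrt(np.sum(w * (err**2).sum(axis=1)))


class TestStabilizationParams:
    def test_pure_lagrangian_cell(self):
        """U = M makes the relative-velocity term vanish: d1 = k1 k / rho."""
        U = np.array([[1.0, 2.0]])
        rho = np.array([1060.0])
        d1, d2 = stabilization_params(U, U, rho, np.array([0.01]), k=1e-3)
        assert d1[0] == pytest.approx(1e-3 / 1060.0)

    def test_zero_velocity_kills_delta2(self):
        d1, d2 = stabilization_params(
            np.zeros((1, 2)), np.zeros((1, 2)), np.array([1.0]),
            np.array([0.1]), k=0.01,
        )
        assert d2[0] == 0.0

    def test_values_match_direct_arithmetic(self):
        """rho=1060, h=0.01, k=1e-3, |U-M|=1, kappa=1: direct formula check."""
        U = np.array([[1.0, 0.0]])
        M = np.zeros((1, 2))
        rho = np.array([1060.0])
        h = np.array([0.01])
        d1, d2 = stabilization_params(U, M, rho, h, k=1e-3)
        exp_d1 = (1 / 1060.0) * (1e-3**-2 + 1.0 / 0.01**2) ** -0.5
        exp_d2 = 1060.0 * 0.01 * 1.0
        assert d1[0] == pytest.approx(exp_d1, rel=1e-12)
        assert d2[0] == pytest.approx(exp_d2, rel=1e-12)


class TestCflTimestep:
    def test_uniform_speed_formula(self):
        mesh = unit_square_mesh(10)
        U = np.zeros((mesh.num_vertices, 2))
        U[:, 0] = 1.0
        h = cell_diameters(mesh)
        dt = cfl_timestep(U, np.zeros_like(U), h, mesh.cells, 0.5)
        assert dt == pytest.approx(0.5 * h.min())

    def test_quiescent_hits_dt_cap(self):
        mesh = unit_square_mesh(4)
        Z = np.zeros((mesh.num_vertices, 2))
        dt = cfl_timestep(Z, Z, cell_diameters(mesh), mesh.cells, 0.5, dt_max=0.01)
        assert dt == 0.01

    def test_recomputed_cfl_equals_target(self, rng):
        """Self-consistency: max |U-M| dt / h over cells returns the target."""
        mesh = unit_square_mesh(6)
        U = rng.normal(size=(mesh.num_vertices, 2))
        M = 0.3 * rng.normal(size=(mesh.num_vertices, 2))
        h = cell_diameters(mesh)
        dt = cfl_timestep(U, M, h, mesh.cells, 0.5)
        rel = np.linalg.norm(U - M, axis=1)
        cfl = (rel[mesh.cells].max(axis=1) * dt / h).max()
        assert cfl == pytest.approx(0.5, rel=1e-12)


class TestSolveLinear:
    def test_identity(self):
        b = np.array([1.0, -2.0, 3.0])
        x = solve_linear(sp.eye(3, format="csr"), b)
        assert np.allclose(x, b)

    def test_spd_poisson_recovered_to_tol(self, rng):
        n = 50
        main = 2.0 * np.ones(n)
        A = sp.diags([-np.ones(n - 1), main, -np.ones(n - 1)], [-1, 0, 1],
                     format="csr")
        x_exact = rng.normal(size=n)
        x = solve_linear(A, A @ x_exact, tol=1e-12)
        assert np.linalg.norm(x - x_exact) < 1e-8

    def test_singular_matrix_signals(self):
        A = sp.csr_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
        with pytest.raises(NonConvergenceError):
            solve_linear(A, np.array([1.0, 0.0]))

    def test_direct_method(self, rng):
        A = sp.csr_matrix(np.diag([1.0, 2.0, 4.0]))
        b = rng.normal(size=3)
        assert np.allclose(solve_linear(A, b, method="direct"), b / [1, 2, 4])


class TestFreeStreamPreservation:
    def test_uniform_translation_is_exact_steady_state(self):
        """With M = U = c the assembled residual of the exact state is ~0."""
        case = make_uniform_advection(n=6)
        mesh, c = case["mesh"], case["velocity"]
        nv = mesh.num_vertices
        st = State.zeros(mesh)
        st.U[:] = c
        st.M[:] = c
        A, b = assemble_system(
            mesh, np.ones(mesh.num_cells), case["materials"], st, st.U, st.M,
            dt=0.01,
        )
        x = np.concatenate([np.full(nv, c[0]), np.full(nv, c[1]), np.zeros(nv)])
        rel = np.linalg.norm(A @ x - b) / max(np.linalg.norm(b), 1.0)
        assert rel < 1e-10


class TestCouette:
    def test_linear_profile_is_invariant(self):
        """The exact linear profile is a fixed point of the time stepping."""
        case = make_couette(n=8)
        mesh = case["mesh"]
        st = State.zeros(mesh)
        st.U = case["exact_U"](mesh.vertices)
        cfg = SolverConfig(krylov="direct")
        theta = np.ones(mesh.num_cells)
        for _ in range(5):
            st, _ = picard_step(mesh, st, theta, case["materials"], 0.05,
                                case["bcs"], cfg)
        err = np.abs(st.U - case["exact_U"](mesh.vertices)).max()
        assert err < 1e-10

    def test_steady_state_from_rest_reproduces_profile(self):
        """Marching from rest converges to the exact P1-representable flow."""
        case = make_couette(n=8)
        mesh = case["mesh"]
        st = State.zeros(mesh)
        cfg = SolverConfig(krylov="direct")
        theta = np.ones(mesh.num_cells)
        for _ in range(150):
            st, _ = picard_step(mesh, st, theta, case["materials"], 0.05,
                                case["bcs"], cfg)
        err = np.abs(st.U - case["exact_U"](mesh.vertices)).max()
        assert err < 1e-8


class TestManufacturedConvergence:
    def test_l2_error_at_least_halves_per_refinement(self):
        """Forced Taylor-Green: spatial L2 velocity error ratio >= 2 per
        mesh halving over three refinements (observed rate ~ 2nd order)."""
        errs = []
        for n in (8, 16, 32):
            case = make_taylor_green(n, nu=0.05)
            mesh = case["mesh"]
            st = State.zeros(mesh)
            st.U = case["exact_U"](mesh.vertices)
            cfg = SolverConfig(krylov="direct", picard_tol=1e-10)
            for _ in range(5):
                st, _ = picard_step(
                    mesh, st, np.ones(mesh.num_cells), case["materials"],
                    1e-4, case["bcs"], cfg, body_force=case["body_force"],
                )
            errs.append(l2_velocity_error(mesh, st.U,
                                          case["exact_U"](mesh.vertices)))
        assert errs[0] / errs[1] >= 2.0
        assert errs[1] / errs[2] >= 2.0


class TestPicard:
    def test_stokes_regime_converges_in_two_sweeps(self):
        """At tiny Reynolds number the fixed point is reached immediately."""
        case = make_couette(n=6, lid_speed=1e-6, mu=10.0)
        mesh = case["mesh"]
        st = State.zeros(mesh)
        _, info = picard_step(mesh, st, np.ones(mesh.num_cells),
                              case["materials"], 0.01, case["bcs"],
                              SolverConfig(krylov="direct"))
        assert info["picard_iterations"] <= 2

    def test_dt_to_zero_is_continuous(self):
        """state_new -> state_prev as dt -> 0 (consistency of the stepping).

        The start state must be dynamically compatible (discretely
        divergence-free and boundary-consistent), otherwise the
        incompressibility projection legitimately produces a dt-independent
        impulsive correction; a short march from rest provides one.
        """
        case = make_couette(n=6)
        mesh = case["mesh"]
        st = State.zeros(mesh)
        cfg = SolverConfig(krylov="direct")
        for _ in range(30):
            st, _ = picard_step(mesh, st, np.ones(mesh.num_cells),
                                case["materials"], 0.05, case["bcs"], cfg)
        changes = []
        for dt in (1e-2, 1e-3, 1e-4):
            new, _ = picard_step(mesh, st, np.ones(mesh.num_cells),
                                 case["materials"], dt, case["bcs"], cfg)
            changes.append(np.abs(new.U - st.U).max())
        assert changes[0] > changes[1] > changes[2]
        assert changes[2] < 0.2 * changes[0]

    def test_divergence_raises_step_rejection(self):
        """An absurdly large step on a convective problem must be rejected
        rather than silently returned."""
        case = make_couette(n=6, lid_speed=50.0, mu=1e-6)
        mesh = case["mesh"]
        st = State.zeros(mesh)
        st.U = 50.0 * np.sin(37.0 * mesh.vertices)  # rough non-solution state
        cfg = SolverConfig(krylov="direct", picard_max=8)
        with pytest.raises(StepRejected):
            picard_step(mesh, st, np.ones(mesh.num_cells), case["materials"],
                        1e4, case["bcs"], cfg)

    def test_zero_state_zero_forcing_stays_zero(self):
        mesh = unit_square_mesh(5)
        bv = np.unique(mesh.boundary_facets())
        bcs = BoundaryConditions(bv, np.zeros((len(bv), 2)),
                                 np.array([0]), np.zeros(1))
        st = State.zeros(mesh)
        new, _ = picard_step(mesh, st, np.ones(mesh.num_cells),
                             MaterialConstants(), 0.01, bcs,
                             SolverConfig(krylov="direct"))
        assert np.abs(new.U).max() == 0.0
        assert np.abs(new.P).max() == 0.0


class TestRunSimulation:
    def test_quiescent_box_stays_at_rest(self):
        """No inflow, ten steps: velocity stays zero and the mesh does not
        move (the valve also never spuriously closes during systole)."""
        from valvefsi.geometry import generate_2d_valve_channel
        from valvefsi.solver import run_simulation
        from valvefsi.cycle import CycleConfig

        mesh = generate_2d_valve_channel(80.0, 20.0, 17.0, 1.5, 4.0)
        x0 = mesh.vertices.copy()
        res = run_simulation(
            mesh, MaterialConstants(mu_s=1e6),
            SolverConfig(krylov="direct", dt_max=0.005),
            cycle=CycleConfig(U_peak=0.0, U_reversal=0.0),
            duration=0.05,
        )
        assert res.status == "completed"
        t, cols = res.series.as_arrays()
        assert np.allclose(cols["GOA"], cols["GOA"][0])
        assert np.array_equal(mesh.vertices, x0)  # input mesh untouched

    def test_leaflet_deflects_downstream_under_constant_ramp(self):
        """Forward flow bends the leaflet downstream: the orifice opens
        monotonically during the early ramp."""
        from valvefsi.geometry import generate_2d_valve_channel
        from valvefsi.solver import run_simulation
        from valvefsi.cycle import CycleConfig

        mesh = generate_2d_valve_channel(80.0, 20.0, 17.0, 1.5, 2.0)
        res = run_simulation(
            mesh, MaterialConstants(mu_s=1e6),
            SolverConfig(krylov="direct", dt_max=0.002),
            cycle=CycleConfig(U_peak=0.5, U_reversal=0.3),
            duration=0.1, contact_threshold=0.0045,
        )
        assert res.status == "completed"
        t, cols = res.series.as_arrays()
        goa = cols["GOA"]
        assert goa[-1] > goa[0] + 1e-3  # opened by more than a millimeter
        # monotone once the startup transient (micron scale) has passed
        ramp = t > 0.02
        assert np.all(np.diff(goa[ramp]) > -1e-6)
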