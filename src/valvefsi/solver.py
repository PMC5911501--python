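"""Stabilized P1-P1 ALE solver for the unified continuum model.

The momentum/continuity system

    rho (du/dt + ((u - m) . grad) u) = div tau,     div u = 0,

is discretized with continuous piecewise-linear velocity and pressure on
the moving simplicial mesh.  Midpoint quadrature in time yields a
Crank-Nicolson scheme in the end-of-step velocity U^n through the slab
average Ubar = (U^n + U^{n-1})/2; the pressure is piecewise constant in
time (one unknown per step).  Equal-order elements are admissible thanks to
a simplified Galerkin/least-squares (streamline-diffusion) term

    SD = (d1 [rho ((Ubar - M) . grad) Ubar + grad P],
              rho ((Ubar - M) . grad) v + grad q)
       + (d2 div Ubar, div v),

with per-cell parameters

    d1 = k1 rho^-1 (dt^-2 + |U - M|^2 h^-2)^(-1/2),
    d2 = k2 rho h |U|,

evaluated from previous-step fields.  Each step is linearized by Picard
iteration: the advective velocity and the solid-stress transport terms are
frozen at the previous iterate, while the solid stiffness contribution
2 mu_s eps(Ubar) dt/2 and the fluid viscous stress stay implicit, so every
sweep solves one sparse linear system in (U^n, P^n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .continuum import MaterialConstants, advance_solid_stress
from .errors import NonConvergenceError, SolverError, StepRejected
from .mesh import REGION_FLUID, TaggedMesh, cell_diameters
from .smoothing import p1_gradients


# ---------------------------------------------------------------------------
# state and configuration
# ---------------------------------------------------------------------------

@dataclass
class State:
    """Discrete solution at one time level."""

    U: np.ndarray          # (nv, d) velocity
    P: np.ndarray          # (nv,) pressure
    M: np.ndarray          # (nv, d) mesh velocity
    tau_s: np.ndarray      # (nc, d, d) solid stress (zero on fluid cells)
    t: float = 0.0

    @classmethod
    def zeros(cls, mesh: TaggedMesh, t: float = 0.0) -> "State":
        nv, d = mesh.vertices.shape
        return cls(
            np.zeros((nv, d)), np.zeros(nv), np.zeros((nv, d)),
            np.zeros((mesh.num_cells, d, d)), t,
        )

    def copy(self) -> "State":
        return State(self.U.copy(), self.P.copy(), self.M.copy(),
                     self.tau_s.copy(), self.t)


@dataclass
class SolverConfig:
    kappa1: float = 1.0
    kappa2: float = 1.0
    cfl_target: float = 0.5
    cfl_floor: float = 0.01
    dt_max: float = np.inf
    dt_min: float = 1e-8
    picard_tol: float = 1e-6
    picard_max: int = 50
    #: weight of the implicit incremental solid stress in the momentum
    #: equation: 0.5 is the energy-conserving midpoint value, 1.0 evaluates
    #: the increment at the end of the step and damps cell-scale elastic
    #: oscillations (the stored stress update is unaffected)
    solid_implicitness: float = 1.0
    krylov: str = "bicgstab"       # "bicgstab" | "direct"
    precond: str = "ilu0"
    linear_tol: float = 1e-10
    speed_floor: float = 1e-9      # prevents division by zero in CFL control


@dataclass
class BoundaryConditions:
    """Strong Dirichlet data: velocity per (vertex, component), pressure per vertex."""

    u_vertices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    u_values: np.ndarray = field(default_factory=lambda: np.zeros((0, 1)))
    p_vertices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    p_values: np.ndarray = field(default_factory=lambda: np.zeros(0))


def theta_from_regions(mesh: TaggedMesh) -> np.ndarray:
    """Binary phase per cell: 1 on fluid, 0 on solid (leaflet) cells."""
    return (mesh.region_tags == REGION_FLUID).astype(float)


# ---------------------------------------------------------------------------
# stabilization and time-step control
# ---------------------------------------------------------------------------

def stabilization_params(
    U_prev: np.ndarray,
    M_prev: np.ndarray,
    rho: np.ndarray,
    h_cell: np.ndarray,
    k: float,
    kappa1: float = 1.0,
    kappa2: float = 1.0,
    cells: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell streamline-diffusion parameters (delta1, delta2).

    ``U_prev``/``M_prev`` may be per-cell (nc, d) averages, or vertex fields
    together with ``cells`` for in-place averaging.
    """
    if cells is not None:
        U_prev = U_prev[cells].mean(axis=1)
        M_prev = M_prev[cells].mean(axis=1)
    rel = np.linalg.norm(U_prev - M_prev, axis=1)
    speed = np.linalg.norm(U_prev, axis=1)
    delta1 = kappa1 / rho / np.sqrt(k**-2 + (rel / h_cell) ** 2)
    delta2 = kappa2 * rho * h_cell * speed
    return delta1, delta2


def cfl_timestep(
    U: np.ndarray,
    M: np.ndarray,
    cell_diam: np.ndarray,
    cells: np.ndarray,
    cfl_target: float = 0.5,
    dt_max: float = np.inf,
    speed_floor: float = 1e-9,
) -> float:
    """dt such that max_K |U - M| dt / h_K equals the CFL target.

    Quiescent cells are floored at ``speed_floor`` so the step is capped by
    ``dt_max`` rather than dividing by zero.
    """
    rel = np.linalg.norm(U - M, axis=1)
    cell_speed = np.maximum(rel[cells].max(axis=1), speed_floor)
    return float(min(dt_max, cfl_target * np.min(cell_diam / cell_speed)))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _accumulate(rows, cols, vals, r, c, v):
    rows.append(np.asarray(r).ravel())
    cols.append(np.asarray(c).ravel())
    vals.append(np.asarray(v).ravel())


def assemble_system(
    mesh: TaggedMesh,
    theta: np.ndarray,
    materials: MaterialConstants,
    state_prev: State,
    U_star: np.ndarray,
    M: np.ndarray,
    dt: float,
    bcs: BoundaryConditions | None = None,
    body_force=None,
    kappa1: float = 1.0,
    kappa2: float = 1.0,
    solid_implicitness: float = 1.0,
):
    """Assemble the linear system for one Picard sweep of one time step.

    Unknown ordering: ``[u_x | u_y (| u_z) | p]`` with one block of nv
    entries per component.  The boundary stress from integration by parts
    is dropped (weak dynamic interface constraint and do-nothing outlet);
    Dirichlet rows are imposed strongly.  Returns ``(A_csr, b)``.
    """
    if dt <= 0:
        raise SolverError("time step must be positive")
    nv, d = mesh.vertices.shape
    cells = mesh.cells
    nc = cells.shape[0]
    n1 = d + 1

    G, vol = p1_gradients(mesh.vertices, cells)
    if np.any(vol <= 0):
        raise SolverError("assembly on a mesh with inverted cells")
    h = cell_diameters(mesh)

    rho_c = theta * materials.rho_fluid + (1 - theta) * materials.rho_solid
    # implicit "viscosity": fluid Newtonian + solid incremental stiffness
    visc = theta * materials.mu_f + (1 - theta) * (
        solid_implicitness * dt * materials.mu_s
    )

    Uprev = state_prev.U
    Ubar_star_c = 0.5 * (U_star[cells] + Uprev[cells]).mean(axis=1)
    M_c = M[cells].mean(axis=1)
    a_c = Ubar_star_c - M_c                     # frozen ALE advective velocity
    adv = np.einsum("kd,kjd->kj", a_c, G)       # (a . grad(phi_j)) per cell

    delta1, delta2 = stabilization_params(
        Uprev[cells].mean(axis=1), state_prev.M[cells].mean(axis=1),
        rho_c, h, dt, kappa1, kappa2,
    )

    GG = np.einsum("kid,kjd->kij", G, G)
    w_node = vol[:, None] / n1                  # integral of each basis fn

    # --- blocks acting on the midpoint velocity Ubar (weight 1, split later)
    conv = rho_c[:, None, None] * w_node[:, :, None] * adv[:, None, :]
    visc_iso = (visc * vol)[:, None, None] * GG
    sd1_uu = (delta1 * vol * rho_c**2)[:, None, None] * np.einsum(
        "ki,kj->kij", adv, adv
    )
    B_iso = conv + visc_iso + sd1_uu            # same for every component pair

    rows_u, cols_u, vals_u = [], [], []
    base = [alpha * nv for alpha in range(d)] + [d * nv]
    cell_dofs = [cells + b for b in base]       # velocity comps then pressure

    for alpha in range(d):
        ra = cell_dofs[alpha][:, :, None] * np.ones((1, 1, n1), dtype=np.int64)
        for beta in range(d):
            cb = cell_dofs[beta][:, None, :] * np.ones((1, n1, 1), dtype=np.int64)
            block = np.zeros((nc, n1, n1))
            if alpha == beta:
                block += B_iso
            # symmetric-gradient cross term: visc * G_{j,alpha} G_{i,beta}
            block += (visc * vol)[:, None, None] * np.einsum(
                "ki,kj->kij", G[:, :, beta], G[:, :, alpha]
            )
            # grad-div stabilization d2
            block += (delta2 * vol)[:, None, None] * np.einsum(
                "ki,kj->kij", G[:, :, alpha], G[:, :, beta]
            )
            _accumulate(rows_u, cols_u, vals_u, ra, cb, block)

    B_u = sp.csr_matrix(
        (np.concatenate(vals_u), (np.concatenate(rows_u), np.concatenate(cols_u))),
        shape=((d + 1) * nv, (d + 1) * nv),
    )

    # --- pressure gradient / continuity / pressure-pressure blocks
    rows, cols, vals = [], [], []
    for alpha in range(d):
        ra = cell_dofs[alpha][:, :, None] * np.ones((1, 1, n1), dtype=np.int64)
        cp = cell_dofs[d][:, None, :] * np.ones((1, n1, 1), dtype=np.int64)
        # -(P, div v)  and  d1 (grad P, rho (a.grad) v)
        bl = (
            -np.einsum("k,ki->ki", vol / n1, G[:, :, alpha])[:, :, None]
            * np.ones((1, 1, n1))
            + (delta1 * vol * rho_c)[:, None, None]
            * np.einsum("ki,kj->kij", adv, G[:, :, alpha])
        )
        _accumulate(rows, cols, vals, ra, cp, bl)
        # continuity rows: (div Ubar, q) + d1 (rho (a.grad) Ubar, grad q)
        rp = cell_dofs[d][:, :, None] * np.ones((1, 1, n1), dtype=np.int64)
        ca = cell_dofs[alpha][:, None, :] * np.ones((1, n1, 1), dtype=np.int64)
        bl = (
            np.einsum("k,kj->kj", vol / n1, G[:, :, alpha])[:, None, :]
            * np.ones((1, n1, 1))
            + (delta1 * vol * rho_c)[:, None, None]
            * np.einsum("ki,kj->kij", G[:, :, alpha], adv)
        )
        _accumulate(rows, cols, vals, rp, ca, bl)
    # d1 (grad P, grad q)
    rp = cell_dofs[d][:, :, None] * np.ones((1, 1, n1), dtype=np.int64)
    cp = cell_dofs[d][:, None, :] * np.ones((1, n1, 1), dtype=np.int64)
    _accumulate(rows, cols, vals, rp, cp, (delta1 * vol)[:, None, None] * GG)

    B_p = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=((d + 1) * nv, (d + 1) * nv),
    )

    # --- lumped mass rho/dt
    mass = np.zeros(nv)
    np.add.at(mass, cells.ravel(), np.repeat(rho_c * vol / n1, n1))
    mass_diag = np.concatenate([mass / dt] * d + [np.zeros(nv)])
    Mass = sp.diags(mass_diag)

    # split: terms acting on the velocity act on Ubar = (U^n + U^{n-1})/2
    # (weight 1/2 on U^n plus a known contribution of U^{n-1} to the rhs);
    # pressure columns keep full weight (P is piecewise constant in time)
    B_p_u = B_p.tolil(copy=True)
    B_p_u[:, d * nv:] = 0
    B_p_u = B_p_u.tocsr()
    B_p_p = B_p - B_p_u
    A = Mass + 0.5 * (B_u + B_p_u) + B_p_p

    x_prev = np.concatenate([Uprev[:, a] for a in range(d)] + [np.zeros(nv)])
    b = Mass @ x_prev - 0.5 * ((B_u + B_p_u) @ x_prev)

    # --- explicit solid stress (previous tau_s + frozen transport terms)
    solid = theta < 0.5
    if np.any(solid):
        g_star = np.einsum("kjd,kje->kde", U_star[cells] * 0.5 + Uprev[cells] * 0.5, G)
        # g_star[k] = grad(Ubar*) with components (d x d): dU_a/dx_b
        tau = state_prev.tau_s
        S = tau + 0.5 * dt * (g_star @ tau + tau @ np.swapaxes(g_star, 1, 2))
        S = np.where(solid[:, None, None], S, 0.0)
        fvec = -np.einsum("k,kab,kib->kia", vol, S, G)  # -(S : grad v)
        for alpha in range(d):
            np.add.at(b, cell_dofs[alpha].ravel(), fvec[:, :, alpha].ravel())

    # --- optional body force (manufactured solutions), lumped at vertices
    if body_force is not None:
        fv = np.asarray(body_force(mesh.vertices, state_prev.t + dt))
        rhof = np.zeros(nv)
        np.add.at(rhof, cells.ravel(), np.repeat(rho_c * vol / n1, n1))
        for alpha in range(d):
            b[alpha * nv:(alpha + 1) * nv] += rhof * fv[:, alpha]

    # --- strong Dirichlet rows
    if bcs is not None:
        dir_rows = []
        dir_vals = []
        if len(bcs.u_vertices):
            for alpha in range(d):
                dir_rows.append(bcs.u_vertices + alpha * nv)
                dir_vals.append(bcs.u_values[:, alpha])
        if len(bcs.p_vertices):
            dir_rows.append(bcs.p_vertices + d * nv)
            dir_vals.append(bcs.p_values)
        if dir_rows:
            dir_rows = np.concatenate(dir_rows)
            dir_vals = np.concatenate(dir_vals)
            A = A.tolil()
            A[dir_rows, :] = 0.0
            A[dir_rows, dir_rows] = 1.0
            A = A.tocsr()
            b[dir_rows] = dir_vals

    return A.tocsr(), b


# ---------------------------------------------------------------------------
# linear solver contract
# ---------------------------------------------------------------------------

def solve_linear(
    A: sp.spmatrix,
    b: np.ndarray,
    tol: float = 1e-10,
    method: str = "bicgstab",
    precond: str = "ilu0",
    maxiter: int = 2000,
) -> np.ndarray:
    """Solve A x = b to a relative residual tolerance.

    Default mirrors a Bi-CGStab/ILU(0) Krylov setup; ``method="direct"``
    selects a sparse LU factorization.  Raises :class:`NonConvergenceError`
    with iteration diagnostics on breakdown.
    """
    b = np.asarray(b, dtype=float)
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return np.zeros_like(b)
    if method == "direct":
        x = spla.spsolve(sp.csc_matrix(A), b)
        if not np.all(np.isfinite(x)):
            raise NonConvergenceError("direct solve produced non-finite values",
                                      {"method": "direct"})
        return x

    Mop = None
    if precond == "ilu0":
        try:
            ilu = spla.spilu(sp.csc_matrix(A), drop_tol=0.0, fill_factor=1.0)
            Mop = spla.LinearOperator(A.shape, ilu.solve)
        except RuntimeError:
            Mop = None  # singular pivot: fall through unpreconditioned
    it = [0]

    def cb(_):
        it[0] += 1

    x, info = spla.bicgstab(A, b, rtol=tol, atol=tol * bnorm, M=Mop,
                            maxiter=maxiter, callback=cb)
    res = np.linalg.norm(A @ x - b) / bnorm
    if info != 0 or not np.isfinite(res) or res > max(10 * tol, 1e-8):
        raise NonConvergenceError(
            f"Bi-CGStab failed (info={info}, rel. residual={res:.3e})",
            {"iterations": it[0], "info": info, "residual": res},
        )
    return x


def _solve_with_fallback(A, b, cfg: SolverConfig):
    if cfg.krylov == "direct":
        return solve_linear(A, b, cfg.linear_tol, "direct")
    try:
        return solve_linear(A, b, cfg.linear_tol, cfg.krylov, cfg.precond)
    except NonConvergenceError:
        return solve_linear(A, b, cfg.linear_tol, "direct")


# ---------------------------------------------------------------------------
# one time step (Picard) and the run loop
# ---------------------------------------------------------------------------

def picard_step(
    mesh: TaggedMesh,
    state_prev: State,
    theta: np.ndarray,
    materials: MaterialConstants,
    dt: float,
    bcs: BoundaryConditions | None = None,
    config: SolverConfig | None = None,
    body_force=None,
) -> tuple[State, dict]:
    """Advance (U, P, tau_s) one time step by fixed-point iteration.

    The advective velocity and solid-stress transport are re-frozen at each
    sweep until the relative velocity update falls below ``picard_tol``.
    Raises :class:`StepRejected` when the iteration diverges or exhausts its
    budget, so the caller can halve dt.
    """
    cfg = config or SolverConfig()
    nv, d = mesh.vertices.shape
    U_star = state_prev.U.copy()
    M = state_prev.M
    history = []
    U_new, P_new = None, None
    for it in range(cfg.picard_max):
        A, b = assemble_system(
            mesh, theta, materials, state_prev, U_star, M, dt,
            bcs=bcs, body_force=body_force,
            kappa1=cfg.kappa1, kappa2=cfg.kappa2,
            solid_implicitness=cfg.solid_implicitness,
        )
        try:
            x = _solve_with_fallback(A, b, cfg)
        except NonConvergenceError as exc:
            raise StepRejected(f"linear solve failed in Picard sweep {it}") from exc
        U_new = np.column_stack([x[a * nv:(a + 1) * nv] for a in range(d)])
        P_new = x[d * nv:]
        if not np.all(np.isfinite(U_new)):
            raise StepRejected("non-finite velocity iterate")
        denom = max(np.linalg.norm(U_new), 1e-30)
        change = np.linalg.norm(U_new - U_star) / denom
        history.append(change)
        U_star = U_new
        if change < cfg.picard_tol:
            break
        if it > 4 and change > 10.0 * history[0] + 1.0:
            raise StepRejected("diverging Picard iteration")
    else:
        raise StepRejected(
            f"Picard did not converge in {cfg.picard_max} sweeps "
            f"(last change {history[-1]:.3e})"
        )

    # end-of-step solid stress update at the converged midpoint velocity
    G, _ = p1_gradients(mesh.vertices, mesh.cells)
    Ubar = 0.5 * (U_new + state_prev.U)
    g_mid = np.einsum("kjd,kje->kde", Ubar[mesh.cells], G)
    tau_new = np.zeros_like(state_prev.tau_s)
    solid = theta < 0.5
    if np.any(solid):
        tau_new[solid] = advance_solid_stress(
            state_prev.tau_s[solid], g_mid[solid], materials.mu_s, dt
        )
    new = State(U_new, P_new, state_prev.M.copy(), tau_new, state_prev.t + dt)
    return new, {"picard_iterations": len(history), "picard_history": history}


# ---------------------------------------------------------------------------
# full simulation driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    series: object                 # postprocess.TimeSeries
    snapshots: list                # [(mesh_copy, state, theta), ...]
    status: str                    # "completed" | "aborted: ..."
    contact: object                # contact.ContactState
    steps: int = 0
    remeshed: bool = False         # always False: the scheme never remeshes


def _contact_distance(mesh, theta, cfg_method):
    """d_min for the mesh's valve kind (leaflet pairs, or leaflet vs wall)."""
    from .contact import minimal_leaflet_distance, surface_distance, surface_facets

    kind = mesh.metadata.get("kind", "")
    if kind == "channel2d" and mesh.metadata.get("num_leaflets", 1) == 1:
        leaf = surface_facets(mesh, 2)
        if len(leaf) == 0:
            return np.inf
        # facing wall: the top-wall facets across the gap
        wall = np.asarray(mesh.facet_tags.get("wall", []))
        H = mesh.metadata["channel"][1]
        top = wall[[np.all(mesh.vertices[f][:, 1] > 0.5 * H) for f in wall]]
        return surface_distance(mesh, leaf, top, cfg_method)
    return minimal_leaflet_distance(mesh, theta, method=cfg_method)


def run_simulation(
    mesh: TaggedMesh,
    materials: MaterialConstants | None = None,
    solver: SolverConfig | None = None,
    smoothing=None,
    cycle=None,
    duration: float | None = None,
    contact_enabled: bool = True,
    contact_threshold: float | None = None,
    contact_method: str = "geometric",
    store_every: int = 0,
    on_step=None,
) -> SimulationResult:
    """Advance the coupled valve problem through one or more cardiac cycles.

    Per accepted step: (1) cycle events and contact release, (2) collision
    detection and phase-switch closure, (3) the momentum/continuity Picard
    solve, (4) linear (and, when triggered, nonlinear quality) mesh
    smoothing plus the coordinate update x += dt M, (5) post-processing of
    the orifice area and the CSV series.  Rejected steps (Picard failure or
    a would-be inverted cell) halve dt down to ``dt_min``; dt recovers by
    doubling after ten accepted steps, always capped by the CFL target.
    """
    from .contact import ContactState, check_and_close, release_contact
    from .cycle import CycleConfig, apply_bcs
    from .cycle import cycle_events as _cycle_events
    from .mesh import quality_all
    from .postprocess import TimeSeries, geometric_orifice_area
    from .smoothing import SmoothingConfig, linear_smooth, nonlinear_smooth
    from .cycle import inflow_magnitude

    mesh = mesh.copy()
    mat = materials or MaterialConstants()
    scfg = solver or SolverConfig(krylov="direct")
    smcfg = smoothing or SmoothingConfig()
    ccfg = cycle or CycleConfig()
    duration = ccfg.T_cycle if duration is None else duration

    theta = theta_from_regions(mesh)
    state = State.zeros(mesh)
    h = cell_diameters(mesh)
    if contact_threshold is None:
        contact_threshold = 2.0 * float(h.min())
    cstate = ContactState(threshold=contact_threshold)
    has_closure = len(mesh.facet_tags.get("closure", [])) > 0
    has_leaflets = np.any(mesh.region_tags != REGION_FLUID)
    do_contact = contact_enabled and has_closure and has_leaflets

    dt_cap = scfg.dt_max if np.isfinite(scfg.dt_max) else ccfg.T_cycle / 400.0
    dt = dt_cap
    series = TimeSeries()
    snapshots = []
    accepted_since_reject = 0
    status = "completed"
    step = 0

    while state.t < duration - 1e-12:
        dt = min(dt, duration - state.t)
        t_new = state.t + dt

        # (1) cycle events: contact release at the start of systole
        events = [name for name, _ in _cycle_events(state.t, t_new, ccfg)]
        if "systole_start" in events and cstate.closed:
            theta, cstate = release_contact(theta, cstate, state.tau_s)

        # (2) collision detection and closure; detection is armed once the
        # systolic pulse has passed (the valve closes under decelerating or
        # reversed flow, never during ejection)
        d_min = np.inf
        armed = (t_new % ccfg.T_cycle) > ccfg.T_systole
        if do_contact:
            if not cstate.closed:
                d_min = _contact_distance(mesh, theta, contact_method)
                if armed:
                    theta, cstate = check_and_close(mesh, theta, cstate, d_min)
            else:
                d_min = cstate.d_min

        # (3) momentum + continuity
        bcs = apply_bcs(mesh, t_new, ccfg)
        try:
            new_state, info = picard_step(mesh, state, theta, mat, dt, bcs, scfg)
        except StepRejected:
            dt *= 0.5
            accepted_since_reject = 0
            if dt < scfg.dt_min:
                status = "aborted: time step underflow"
                break
            continue

        # (4) mesh velocity smoothing and coordinate update
        solid_vs = (
            np.unique(mesh.cells[theta < 0.5]) if np.any(theta < 0.5)
            else np.array([], dtype=np.int64)
        )
        iface_vel = np.zeros_like(new_state.U)
        if len(solid_vs):
            iface_vel[solid_vs] = new_state.U[solid_vs]
        M = linear_smooth(mesh, iface_vel)
        if len(solid_vs):
            M[solid_vs] = new_state.U[solid_vs]
        trial = mesh.vertices + dt * M
        q = quality_all(trial, mesh.cells)
        if not np.all(np.isfinite(q)):
            dt *= 0.5
            accepted_since_reject = 0
            if dt < scfg.dt_min:
                status = "aborted: mesh inverted and dt underflowed"
                break
            continue
        old_coords = mesh.vertices
        mesh.vertices = trial
        if q.max() > smcfg.quality_trigger:
            smoothed, ok = nonlinear_smooth(mesh, smcfg)
            mesh.vertices = smoothed
            if not ok and quality_all(mesh.vertices, mesh.cells).max() > smcfg.max_quality:
                status = "aborted: unrecoverable mesh degeneration"
                break
        # mesh velocity consistent with the total committed motion
        new_state.M = (mesh.vertices - old_coords) / dt
        state = new_state
        accepted_since_reject += 1
        step += 1

        # (5) post-processing
        goa = (
            geometric_orifice_area(mesh, theta) if has_closure else np.nan
        )
        series.append(
            state.t,
            GOA=goa,
            d_min=d_min,
            dt=dt,
            closed=float(cstate.closed),
            inflow=inflow_magnitude(state.t, ccfg),
            picard=info["picard_iterations"],
            Q_max=float(quality_all(mesh.vertices, mesh.cells).max()),
        )
        if store_every and step % store_every == 0:
            snapshots.append((mesh.copy(), state.copy(), theta.copy()))
        if on_step is not None:
            on_step(mesh, state, theta, cstate)

        # dt control: CFL with recovery doubling
        dt_cfl = cfl_timestep(
            state.U, state.M, cell_diameters(mesh), mesh.cells,
            scfg.cfl_target, dt_cap, scfg.speed_floor,
        )
        if accepted_since_reject >= 10:
            dt = min(2.0 * dt, dt_cfl)
        else:
            dt = min(dt, dt_cfl)

    return SimulationResult(series, snapshots, status, cstate, step)
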