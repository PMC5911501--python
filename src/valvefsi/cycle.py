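"""Cardiac-cycle boundary conditions, phase events and leaflet pre-stress.

One heart cycle lasts 1.124 s and contains only the two major phases:
systole, during which a flat-profile inflow pulse drives the valve open,
and diastole, during which the inflow is zero and the closed valve holds
the domain.  At the end of systole the inflow direction is inverted for a
short reversal window (~0.05 s) — the physiological backflow that completes
valve closure.  The default waveform is a half-sine forward pulse followed
by a half-sine reversal lobe; peak magnitude, durations and the reversal
magnitude are all configurable.

Native-valve simulations start from a pre-stressed configuration: a
constant radial stress is prescribed in the leaflets so the material
contracts like a stretched balloon, the structure is relaxed to
equilibrium, and the accumulated stress is then reset before the FSI run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .continuum import MaterialConstants
from .errors import ConfigurationError, NonConvergenceError
from .mesh import TaggedMesh
from .smoothing import linear_smooth
from .solver import BoundaryConditions, SolverConfig, State, picard_step, theta_from_regions


@dataclass
class CycleConfig:
    T_cycle: float = 1.124     # s
    T_systole: float = 0.4     # s, forward half-sine pulse
    T_reversal: float = 0.05   # s, reversed-flow lobe closing the valve
    U_peak: float = 1.0        # m/s
    U_reversal: float = 0.3    # m/s
    ramp: str = "half_sine"

    def __post_init__(self):
        if min(self.T_cycle, self.T_systole, self.T_reversal) <= 0:
            raise ConfigurationError("cycle durations must be positive")
        if self.T_systole + self.T_reversal >= self.T_cycle:
            raise ConfigurationError("systole + reversal must fit inside the cycle")


@dataclass
class PreStressConfig:
    sigma_r: float = 4.0       # Pa, initial radial leaflet stress
    max_steps: int = 200
    dt: float = 1e-3           # pseudo-dynamic relaxation step (s)
    tol: float = 1e-8          # max vertex displacement per step (m)


def inflow_magnitude(t: float, config: CycleConfig | None = None) -> float:
    """Signed flat-profile inflow speed at time t (periodic in T_cycle)."""
    cfg = config or CycleConfig()
    tau = t % cfg.T_cycle
    if tau < cfg.T_systole:
        return cfg.U_peak * np.sin(np.pi * tau / cfg.T_systole)
    tau -= cfg.T_systole
    if tau < cfg.T_reversal:
        return -cfg.U_reversal * np.sin(np.pi * tau / cfg.T_reversal)
    return 0.0


_EVENT_OFFSETS = (
    ("cycle_start", 0.0),
    ("systole_start", 0.0),
    ("reversal_start", None),   # T_systole
    ("diastole_start", None),   # T_systole + T_reversal
)


def cycle_events(t_prev: float, t_new: float, config: CycleConfig | None = None):
    """Phase boundaries crossed in (t_prev, t_new], in chronological order.

    Each event appears exactly once per cycle; cycle_start precedes the
    coincident systole_start.
    """
    cfg = config or CycleConfig()
    offsets = [
        ("cycle_start", 0.0),
        ("systole_start", 0.0),
        ("reversal_start", cfg.T_systole),
        ("diastole_start", cfg.T_systole + cfg.T_reversal),
    ]
    events = []
    n0 = int(np.floor(t_prev / cfg.T_cycle))
    n1 = int(np.floor(t_new / cfg.T_cycle)) + 1
    for n in range(n0, n1 + 1):
        for rank, (name, off) in enumerate(offsets):
            t_ev = n * cfg.T_cycle + off
            if t_prev < t_ev <= t_new:
                events.append((t_ev, rank, name))
    events.sort()
    return [(name, t_ev) for t_ev, _, name in events]


def inflow_direction(mesh: TaggedMesh) -> np.ndarray:
    """Unit inflow direction from the mesh's axis metadata."""
    axis = mesh.metadata.get("axis", "z" if mesh.dim == 3 else "x")
    e = np.zeros(mesh.dim)
    e[{"x": 0, "y": 1, "z": 2}[axis]] = 1.0
    return e


def apply_bcs(
    mesh: TaggedMesh,
    t: float,
    config: CycleConfig | None = None,
    extra_zero_vertices: np.ndarray | None = None,
) -> BoundaryConditions:
    """Strong boundary data at time t.

    Inlet: flat profile of magnitude ``inflow_magnitude(t)`` along the
    domain axis.  Walls: no slip (the outer wall mesh is fixed).  Outlet:
    homogeneous Dirichlet pressure; the viscous boundary term is dropped in
    assembly, so the outlet traction reduces to the prescribed pressure.
    Wall values override inlet values on shared rim vertices.
    """
    cfg = config or CycleConfig()
    inlet = mesh.tagged_vertices("inlet")
    wall = mesh.tagged_vertices("wall")
    outlet = mesh.tagged_vertices("outlet")
    if len(inlet) == 0 or len(outlet) == 0:
        raise ConfigurationError("mesh lacks inlet/outlet facet tags")

    mag = inflow_magnitude(t, cfg)
    direction = inflow_direction(mesh)

    verts = [inlet, wall]
    vals = [np.tile(mag * direction, (len(inlet), 1)),
            np.zeros((len(wall), mesh.dim))]
    if extra_zero_vertices is not None and len(extra_zero_vertices):
        verts.append(extra_zero_vertices)
        vals.append(np.zeros((len(extra_zero_vertices), mesh.dim)))
    uv = np.concatenate(verts)
    uvals = np.vstack(vals)
    # later entries win: build unique with reversed priority
    _, last_idx = np.unique(uv[::-1], return_index=True)
    keep = len(uv) - 1 - last_idx
    return BoundaryConditions(
        u_vertices=uv[keep],
        u_values=uvals[keep],
        p_vertices=outlet,
        p_values=np.zeros(len(outlet)),
    )


# ---------------------------------------------------------------------------
# pre-stress initialization
# ---------------------------------------------------------------------------

def radial_directions(mesh: TaggedMesh, cells_idx: np.ndarray) -> np.ndarray:
    """Unit radial direction (from the valve axis) per selected cell."""
    cent = mesh.vertices[mesh.cells[cells_idx]].mean(axis=1)
    if mesh.dim == 3:
        r = cent[:, :2].copy()
    else:
        # 2D analog: "radial" means along the channel axis (the direction a
        # contracting leaflet shortens in)
        r = np.zeros((len(cent), 2))
        r[:, 0] = 1.0
        return r
    norm = np.maximum(np.linalg.norm(r, axis=1), 1e-12)
    e = np.zeros((len(cent), 3))
    e[:, :2] = r / norm[:, None]
    return e


def prestress_initialize(
    mesh: TaggedMesh,
    config: PreStressConfig | None = None,
    materials: MaterialConstants | None = None,
    solver_config: SolverConfig | None = None,
) -> tuple[TaggedMesh, dict]:
    """Relax the leaflets under a constant radial pre-stress.

    Sets tau_s = sigma_r * (e_r x e_r) in every leaflet cell, advances the
    coupled system with zero inflow until the maximal vertex displacement
    per pseudo step falls below the tolerance, resets tau_s, and returns
    the deformed mesh as the simulation's start configuration.
    """
    cfg = config or PreStressConfig()
    mat = materials or MaterialConstants()
    scfg = solver_config or SolverConfig(krylov="direct")
    out = mesh.copy()
    if cfg.sigma_r == 0.0:
        return out, {"steps": 0, "max_displacement": 0.0}

    theta = theta_from_regions(out)
    solid = np.flatnonzero(theta < 0.5)
    state = State.zeros(out)
    e_r = radial_directions(out, solid)
    state.tau_s[solid] = cfg.sigma_r * np.einsum("ka,kb->kab", e_r, e_r)

    inlet = out.tagged_vertices("inlet")
    wall = out.tagged_vertices("wall")
    outlet = out.tagged_vertices("outlet")
    uv = np.unique(np.concatenate([inlet, wall]))
    bcs = BoundaryConditions(uv, np.zeros((len(uv), out.dim)),
                             outlet, np.zeros(len(outlet)))

    last_disp = np.inf
    solid_vs = np.unique(out.cells[out.region_tags != 1])
    for step in range(cfg.max_steps):
        new_state, _ = picard_step(out, state, theta, mat, cfg.dt, bcs, scfg)
        iface_vel = np.zeros_like(new_state.U)
        iface_vel[solid_vs] = new_state.U[solid_vs]
        M = linear_smooth(out, iface_vel)
        M[solid_vs] = new_state.U[solid_vs]
        disp = cfg.dt * M
        out.vertices = out.vertices + disp
        new_state.M = M
        state = new_state
        last_disp = float(np.abs(disp).max())
        if last_disp < cfg.tol:
            break
    else:
        raise NonConvergenceError(
            "pre-stress relaxation did not reach equilibrium",
            {"last_displacement": last_disp, "steps": cfg.max_steps},
        )
    return out, {"steps": step + 1, "max_displacement": last_disp}
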