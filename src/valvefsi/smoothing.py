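"""ALE mesh-velocity smoothing.

Two cooperating smoothers keep the moving mesh usable without remeshing:

* :func:`linear_smooth` — a componentwise Poisson (linear elastic) solve in
  the fluid region for the mesh velocity, with the structure velocity as
  Dirichlet data on the fluid-structure interface and zero motion on fixed
  outer boundaries.  Cheap, run every step.
* :func:`nonlinear_smooth` — pseudo-time gradient descent on the
  quality-weighted elastic energy  E = sum_K vol_K * Q(K).  Since
  Q = ||F||_F^2 / (d det(F)^{2/d}) is the isochoric neo-Hookean energy
  density tr(C_bar)/d of the cell-to-reference deformation, descending on
  E is a nonlinear elasticity relaxation whose stiffness grows with cell
  distortion.  Steps that would invert a cell or raise the worst quality
  are rejected with a halved pseudo step, so Q_max is non-increasing and no
  inverted cell is ever committed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import SolverError
from .mesh import (
    TaggedMesh,
    _REF_INV,
    cell_volumes,
    quality_all,
)


@dataclass
class SmoothingConfig:
    pseudo_steps: int = 5          # nonlinear pseudo-time step budget per call
    pseudo_dt: float = 0.2         # dimensionless descent step
    quality_trigger: float = 8.0   # run the nonlinear smoother above this Q_max
    max_quality: float = 50.0      # abort threshold for the caller

    def __post_init__(self):
        if self.pseudo_steps < 0:
            raise ValueError("pseudo_steps must be non-negative")
        if self.quality_trigger <= 1.0 or self.max_quality <= 1.0:
            raise ValueError("quality thresholds must exceed 1")


def p1_gradients(vertices: np.ndarray, cells: np.ndarray):
    """Per-cell P1 basis gradients (nc, d+1, d) and volumes (nc,)."""
    d = vertices.shape[1]
    p = vertices[cells]
    E = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)  # (nc, d, d)
    from math import factorial

    vol = np.linalg.det(E) / factorial(d)
    Einv = np.linalg.inv(E)  # rows of Einv are gradients of lambda_1..d
    G = np.empty((cells.shape[0], d + 1, d))
    G[:, 1:, :] = Einv
    G[:, 0, :] = -Einv.sum(axis=1)
    return G, vol


def stiffness_matrix(vertices, cells, nv=None):
    """P1 Laplacian assembled over the given cells."""
    nv = vertices.shape[0] if nv is None else nv
    G, vol = p1_gradients(vertices, cells)
    local = np.einsum("kid,kjd,k->kij", G, G, vol)
    d1 = cells.shape[1]
    rows = np.repeat(cells, d1, axis=1).ravel()
    cols = np.tile(cells, (1, d1)).ravel()
    return sp.csr_matrix((local.ravel(), (rows, cols)), shape=(nv, nv))


def linear_smooth(
    mesh: TaggedMesh,
    interface_velocity: np.ndarray,
    fixed_boundary_tags: tuple = ("inlet", "outlet", "wall"),
    material_velocity: np.ndarray | None = None,
) -> np.ndarray:
    """Harmonic extension of the interface velocity into the fluid region.

    ``interface_velocity`` is a full (nv, d) array whose values on the
    interface vertices are the structure velocity.  Returns the mesh
    velocity M on all vertices: the Poisson solution on fluid vertices,
    the structure velocity on interface/solid vertices, zero on fixed
    boundaries.
    """
    nv, d = mesh.vertices.shape
    fluid_cells = mesh.cells[mesh.region_tags == 1]
    if fluid_cells.size == 0:
        raise SolverError("fluid region is empty")
    K = stiffness_matrix(mesh.vertices, fluid_cells, nv)

    M = np.zeros((nv, d))
    solid_vs = np.unique(mesh.cells[mesh.region_tags != 1]) if np.any(
        mesh.region_tags != 1
    ) else np.array([], dtype=np.int64)
    iface_vs = mesh.tagged_vertices("interface")
    fixed_vs = np.unique(np.concatenate(
        [mesh.tagged_vertices(t) for t in fixed_boundary_tags]
        + [np.array([], dtype=np.int64)]
    ))

    dirichlet = np.zeros(nv, dtype=bool)
    vel = material_velocity if material_velocity is not None else interface_velocity
    for vs, vals in ((fixed_vs, None), (solid_vs, vel), (iface_vs, interface_velocity)):
        if len(vs) == 0:
            continue
        dirichlet[vs] = True
        if vals is not None:
            M[vs] = vals[vs]

    active = np.zeros(nv, dtype=bool)
    active[np.unique(fluid_cells)] = True
    free = active & ~dirichlet
    if not free.any():
        return M
    idx_free = np.flatnonzero(free)
    idx_dir = np.flatnonzero(dirichlet & active)
    Kff = K[idx_free][:, idx_free]
    Kfd = K[idx_free][:, idx_dir]
    if Kff.shape[0] and abs(Kff.diagonal()).min() == 0.0:
        raise SolverError("disconnected fluid component without Dirichlet data")
    try:
        sol = spla.spsolve(Kff.tocsc(), -Kfd @ M[idx_dir])
    except RuntimeError as exc:  # pragma: no cover - factorization failure
        raise SolverError(f"linear smoother solve failed: {exc}") from exc
    M[idx_free] = sol.reshape(len(idx_free), d)
    return M


# ---------------------------------------------------------------------------
# nonlinear quality-driven smoother
# ---------------------------------------------------------------------------

def _shape_energy_gradient(vertices, cells):
    """Gradient of E = sum_K vol_K * Q(K) with respect to vertex positions.

    Uses vol_K * Q(K) = tr(F^T F) det(F)^(1-2/d) / d with F the deformation
    gradient against the unit-measure equilateral reference (det F = vol_K).
    """
    d = vertices.shape[1]
    Vinv = _REF_INV[d]
    p = vertices[cells]
    E = np.swapaxes(p[:, 1:, :] - p[:, :1, :], 1, 2)
    F = E @ Vinv
    detF = np.linalg.det(F)
    if np.any(detF <= 0):
        raise SolverError("cannot evaluate shape energy on an inverted mesh")
    trFtF = np.einsum("kij,kij->k", F, F)
    e = 1.0 - 2.0 / d
    FinvT = np.swapaxes(np.linalg.inv(F), 1, 2)
    dWdF = (
        2.0 * F * (detF**e)[:, None, None]
        + (e * trFtF * detF**e)[:, None, None] * FinvT
    ) / d
    dWdE = dWdF @ Vinv.T  # chain rule through F = E Vinv
    grad = np.zeros_like(vertices)
    np.add.at(grad, cells[:, 1:].ravel(),
              np.swapaxes(dWdE, 1, 2).reshape(-1, d))
    np.add.at(grad, cells[:, 0], -dWdE.sum(axis=2))
    energy = float(np.sum(trFtF * detF**e) / d)
    return energy, grad


def movable_fluid_vertices(mesh: TaggedMesh) -> np.ndarray:
    """Interior fluid vertices: everything except boundary, interface, solid."""
    nv = mesh.num_vertices
    frozen = np.zeros(nv, dtype=bool)
    bnd = mesh.boundary_facets()
    if bnd.size:
        frozen[np.unique(bnd)] = True
    frozen[mesh.tagged_vertices("interface")] = True
    solid = mesh.cells[mesh.region_tags != 1]
    if solid.size:
        frozen[np.unique(solid)] = True
    return np.flatnonzero(~frozen)


def nonlinear_smooth(
    mesh: TaggedMesh,
    config: SmoothingConfig | None = None,
    movable: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Relax interior fluid vertices down the quality-weighted elastic energy.

    Returns ``(new_vertices, improved)``; ``improved`` is False when the
    pseudo-step budget could not reduce the worst quality (caller may then
    shrink the physical time step).  The input mesh is not modified.
    """
    cfg = config or SmoothingConfig()
    x = mesh.vertices.copy()
    if cfg.pseudo_steps == 0:
        return x, True
    mv = movable_fluid_vertices(mesh) if movable is None else movable
    if len(mv) == 0:
        return x, True

    q0 = quality_all(x, mesh.cells)
    q_max = q0.max()
    tau = cfg.pseudo_dt
    # normalize the descent step so it is mesh-size independent: the energy
    # curvature per vertex scales like h^(d-2)
    d = mesh.dim
    h_char = float(np.median(cell_volumes(x, mesh.cells)) ** (1.0 / d))
    norm = h_char ** (2 - d)
    improved_any = False
    for _ in range(cfg.pseudo_steps):
        _, grad = _shape_energy_gradient(x, mesh.cells)
        step = np.zeros_like(x)
        step[mv] = -tau * norm * grad[mv]
        accepted = False
        for _ in range(8):
            trial = x + step
            q = quality_all(trial, mesh.cells)
            if np.all(np.isfinite(q)) and q.max() <= q_max * (1 + 1e-12):
                x = trial
                if q.max() < q_max:
                    improved_any = True
                q_max = min(q_max, q.max())
                accepted = True
                break
            tau *= 0.5
            step *= 0.5
        if not accepted:
            break
    return x, improved_any or q_max <= cfg.quality_trigger
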