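"""Unified-continuum constitutive model.

One set of conservation laws covers both blood and leaflet tissue; a binary
per-cell phase function theta selects the constitutive stress:

    tau   = tau_D - p I,
    tau_D = theta * tau_f + (1 - theta) * tau_s,
    tau_f = 2 mu_f eps(u)                      (Newtonian fluid),
    D_t tau_s = 2 mu_s eps(u) + grad(u) tau_s + tau_s grad(u)^T
                                               (rate form of incompressible
                                                neo-Hookean solid),

with eps(u) the symmetric velocity gradient.  Incompressibility of both
phases is enforced by the shared continuity equation, so the rate form above
is the complete solid model — no separate strain-energy function is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValveFsiError


@dataclass
class MaterialConstants:
    """Densities and stiffness/viscosity constants of the two phases.

    Blood is Newtonian with mu_f = 0.0027 Pa*s and rho = 1060 kg/m^3; the
    leaflet tissue is an incompressible neo-Hookean solid.  The native-valve
    default shear modulus is 3.3e9 Pa and the mechanical-valve default is
    6.5e11 Pa; both are stated stand-in stiffnesses rather than measured
    tissue moduli and can be overridden from the material config block.
    """

    rho_fluid: float = 1060.0     # kg/m^3
    rho_solid: float = 1000.0     # kg/m^3
    mu_f: float = 0.0027          # Pa*s
    mu_s: float = 3.3e9           # Pa

    #: BMHV leaflet stiffness (Pa)
    MU_S_BMHV = 6.5e11

    def __post_init__(self):
        if min(self.rho_fluid, self.rho_solid, self.mu_f, self.mu_s) <= 0:
            raise ValueError("material constants must be positive")


def strain_rate(grad_u: np.ndarray) -> np.ndarray:
    """Symmetric part of a velocity gradient: eps(u) = (grad u + grad u^T)/2."""
    g = np.asarray(grad_u, dtype=float)
    return 0.5 * (g + np.swapaxes(g, -1, -2))


def fluid_stress(grad_u: np.ndarray, mu_f: float) -> np.ndarray:
    """Newtonian deviatoric stress tau_f = 2 mu_f eps(u)."""
    return 2.0 * mu_f * strain_rate(grad_u)


def advance_solid_stress(
    tau_s_prev: np.ndarray,
    grad_u_mid: np.ndarray,
    mu_s: float,
    dt: float,
) -> np.ndarray:
    """One explicit step of the solid stress rate equation.

    tau_s^{n} = tau_s^{n-1} + dt * (2 mu_s eps(u) + grad(u) tau_s^{n-1}
                                    + tau_s^{n-1} grad(u)^T)

    with the velocity gradient evaluated at the step midpoint and tau_s on
    the right-hand side frozen at the previous level.  The result is
    symmetrized so round-off cannot accumulate asymmetry.  Works on a single
    tensor or batched (n, d, d) arrays.
    """
    tau = np.asarray(tau_s_prev, dtype=float)
    g = np.asarray(grad_u_mid, dtype=float)
    if not (np.all(np.isfinite(tau)) and np.all(np.isfinite(g))):
        raise ValveFsiError("non-finite input to solid stress update")
    rate = 2.0 * mu_s * strain_rate(g) + g @ tau + tau @ np.swapaxes(g, -1, -2)
    new = tau + dt * rate
    return 0.5 * (new + np.swapaxes(new, -1, -2))


def composite_stress(
    theta: float | np.ndarray,
    tau_f: np.ndarray,
    tau_s: np.ndarray,
    p: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Total stress tau = tau_D - p I and the deviatoric blend tau_D.

    theta is the binary phase value (1 fluid, 0 solid); with a binary phase
    the blend is exact selection, no interpolation occurs.
    """
    tau_f = np.asarray(tau_f, dtype=float)
    tau_s = np.asarray(tau_s, dtype=float)
    d = tau_f.shape[-1]
    th = np.asarray(theta, dtype=float)[..., None, None]
    tau_D = th * tau_f + (1.0 - th) * tau_s
    pI = np.asarray(p, dtype=float)[..., None, None] * np.eye(d)
    return tau_D - pI, tau_D


def von_mises(tau: np.ndarray) -> float | np.ndarray:
    """Deviatoric stress magnitude  tau_v = sqrt(sum_ij |tau_ij - delta_ij tr/3|^2).

    Expects symmetric 3x3 tensors; 2D tensors are embedded with a zero third
    row and column before taking the 3D trace, matching the convention used
    for the leaflet stress maps.  Batched (n, d, d) input returns (n,).
    """
    t = np.asarray(tau, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    if t.shape[-1] == 2:
        t3 = np.zeros(t.shape[:-2] + (3, 3))
        t3[..., :2, :2] = t
        t = t3
    tr = np.trace(t, axis1=-2, axis2=-1)
    dev = t - tr[..., None, None] / 3.0 * np.eye(3)
    tv = np.sqrt(np.einsum("...ij,...ij->...", dev, dev))
    return float(tv[0]) if single else tv
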