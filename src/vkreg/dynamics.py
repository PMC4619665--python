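"""Damped explicit dynamics and static solves for the three FE models.

The nonlinear model (NFEM) relaxes M u'' + C u' + F(u) = R to equilibrium
with the central-difference scheme

    (M/dt^2 + C/2dt) u_{t+1} = R - F + (2M/dt^2) u_t + (C/2dt - M/dt^2) u_{t-1},

where M is the lumped (diagonal) mass matrix with M_ii = rho V_el / 3 per
element node and C = alpha M.  The linear dynamic model (DFEM) replaces
F(u) by K u; the linear static model (LFEM) solves K u = R directly.

Unit system: lengths are in pixels with unit thickness, Young's modulus
enters the constitutive matrix in kPa and is converted to Pa (x 1000)
when forming dynamic forces, and rho is the density per pixel area.  In
these units the default parameter set (E = 100 kPa, rho = 1000,
alpha = 5, dt = 0.004) gives a per-step amplification factor
exp(-alpha dt / 2) = 0.990 for the damped modes and a comfortable
stability margin, so ~500 steps reduce the transient by >99%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elasticity import MaterialParams, elastic_force, linear_stiffness
from .mesh import NodalField, TriMesh

__all__ = [
    "DynamicState",
    "InstabilityError",
    "KPA_TO_BASE",
    "lumped_mass",
    "explicit_step",
    "relax_to_equilibrium",
    "lfem_solve",
]

# kPa -> base force units of the dynamic solver (see module docstring)
KPA_TO_BASE = 1.0e3


class InstabilityError(RuntimeError):
    """Explicit integration diverged (time step too large for the mesh)."""


@dataclass
class DynamicState:
    """Explicit-integration state: displacements at t and t-1 plus lumped
    mass/damping diagonals (per dof)."""

    u_curr: np.ndarray
    u_prev: np.ndarray
    M_diag: np.ndarray
    C_diag: np.ndarray
    t: int = 0

    @classmethod
    def at_rest(cls, mesh: TriMesh, mat: MaterialParams, u0: NodalField) -> "DynamicState":
        M = lumped_mass(mesh, mat)
        u = u0.values.ravel().copy()
        return cls(u, u.copy(), M, mat.alpha * M, 0)


def lumped_mass(mesh: TriMesh, mat: MaterialParams) -> np.ndarray:
    """Per-dof lumped mass vector (2n,): each element gives rho A_el / 3
    to each of its nodes (unit thickness); both dofs share the nodal mass."""
    m_node = np.zeros(mesh.n_nodes)
    contrib = np.repeat(mat.rho * mesh.area / 3.0, 3)
    np.add.at(m_node, mesh.elements.ravel(), contrib)
    return np.repeat(m_node, 2)


def explicit_step(state: DynamicState, F_elastic: np.ndarray, R_external: np.ndarray,
                  mat: MaterialParams) -> DynamicState:
    """One central-difference step; rotates the state in place and returns it."""
    if not (np.all(np.isfinite(F_elastic)) and np.all(np.isfinite(R_external))):
        raise InstabilityError(f"non-finite force input at step {state.t}")
    dt = mat.dt
    a0 = state.M_diag / dt**2
    a1 = state.C_diag / (2.0 * dt)
    u_next = (R_external - F_elastic + 2.0 * a0 * state.u_curr
              + (a1 - a0) * state.u_prev) / (a0 + a1)
    state.u_prev, state.u_curr = state.u_curr, u_next
    state.t += 1
    return state


def relax_to_equilibrium(
    mesh: TriMesh,
    u0: NodalField,
    mat: MaterialParams,
    D: np.ndarray,
    external_force_provider: Callable[[NodalField], NodalField],
    model: Literal["NFEM", "DFEM"] = "NFEM",
    max_steps: int = 500,
    tol: float = 1e-3,
    refresh_interval: int = 10,
    log: list | None = None,
    average_fraction: float = 0.3,
) -> NodalField:
    """Relax the dynamic model to equilibrium against a SEMI force provider.

    The provider maps the current nodal displacement to the nodal external
    force and is re-evaluated every ``refresh_interval`` steps.  Stops when
    the max per-node displacement increment drops below ``tol`` (pixels) or
    after ``max_steps``.  Because the image force landscape is rough at the
    sub-pixel scale, the underdamped trajectory can keep oscillating around
    equilibrium; when the increment tolerance is not reached, the returned
    displacement is the time average over the trailing ``average_fraction``
    of the steps, which cancels the oscillatory component.  Raises
    :class:`InstabilityError` on divergence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    state = DynamicState.at_rest(mesh, mat, u0)
    K = linear_stiffness(mesh, D) * KPA_TO_BASE if model == "DFEM" else None
    diag = float(np.hypot(mesh.width, mesh.height))
    R = external_force_provider(NodalField(state.u_curr.reshape(-1, 2))).values.ravel()
    acc = np.zeros_like(state.u_curr)
    n_acc = 0
    t_avg = int(max_steps * (1.0 - average_fraction))
    converged = False
    for step in range(max_steps):
        u_nf = NodalField(state.u_curr.reshape(-1, 2))
        if model == "NFEM":
            F = elastic_force(mesh, u_nf, D).values.ravel() * KPA_TO_BASE
        else:
            F = K @ state.u_curr
        if step > 0 and step % refresh_interval == 0:
            R = external_force_provider(u_nf).values.ravel()
        prev = state.u_curr
        explicit_step(state, F, R, mat)
        if not np.all(np.isfinite(state.u_curr)) or np.abs(state.u_curr).max() > diag:
            raise InstabilityError(
                f"divergence at step {step} (dt={mat.dt}); reduce dt or force weight"
            )
        if step >= t_avg:
            acc += state.u_curr
            n_acc += 1
        inc = np.abs(state.u_curr - prev).max()
        if log is not None:
            log.append((step, inc))
        if inc < tol:
            converged = True
            break
    if not converged and n_acc > 0:
        return NodalField((acc / n_acc).reshape(-1, 2))
    return NodalField(state.u_curr.reshape(-1, 2))


def lfem_solve(mesh: TriMesh, D: np.ndarray, R_external: NodalField,
               reg: float = 1e-8) -> NodalField:
    """Static linear solve K u = R with a small Tikhonov shift fixing the
    rigid-translation nullspace."""
    K = linear_stiffness(mesh, D) * KPA_TO_BASE
    n2 = K.shape[0]
    lam = reg * (K.diagonal().sum()) / n2
    A = (K + lam * sp.identity(n2, format="csr")).tocsc()
    u = spla.spsolve(A, R_external.values.ravel())
    return NodalField(u.reshape(-1, 2))
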