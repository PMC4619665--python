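"""St. Venant-Kirchhoff elasticity on linear triangular elements.

The material is the simplest hyperelastic law: a linear (Hookean)
constitutive relation applied to the geometrically nonlinear
Green-St.Venant strain

    e = 1/2 (grad u + grad u^T + grad u^T grad u),

which vanishes under arbitrary rigid rotations (the infinitesimal strain
of the linear model does not).  With the displacement-gradient 4-vector
g = [du_X/dX, du_Y/dX, du_X/dY, du_Y/dY], the engineering strain vector
eps = [e_XX, e_YY, 2 e_XY] is

    eps_m = h_m . g + 1/2 g . H_m g,   m = 1, 2, 3,

with constant selector vectors h_m and sparse symmetric matrices H_m.
On P1 triangles g is constant per element, so all element integrals are
exact products of area and density.  The elastic nodal force is the exact
analytic gradient of the total strain energy with respect to the nodal
displacements:

    F_el = A * B^T sum_m (D eps)_m (h_m + H_m g),

polynomial of degree 3 in u (linear + quadratic + cubic terms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mesh import NodalField, TriMesh

__all__ = [
    "MaterialParams",
    "SingularMaterialError",
    "H_MATS",
    "H_VECS",
    "constitutive_matrix",
    "element_b_matrices",
    "displacement_gradient",
    "green_strain",
    "strain_energy",
    "elastic_force",
    "linear_stiffness",
    "element_strains",
]


class SingularMaterialError(ValueError):
    """Poisson ratio at or beyond the incompressible limit (v >= 0.5)."""


@dataclass
class MaterialParams:
    """Elastic material and integration parameters.

    E : Young's modulus, kPa (default 100).
    v : Poisson's ratio (default 0.45, nearly incompressible soft tissue).
    rho : mass density (default 1000).
    alpha : mass-proportional damping scale, C = alpha * M (default 5).
    dt : explicit integration time step (default 0.004).
    """

    E: float = 100.0
    v: float = 0.45
    rho: float = 1000.0
    alpha: float = 5.0
    dt: float = 0.004

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not 0.0 <= self.v < 0.5:
            raise SingularMaterialError(f"Poisson ratio must be in [0, 0.5), got {self.v}")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


# selector vectors h_m and sparse symmetric matrices H_m for
# eps_m = h_m . g + 1/2 g . H_m g
H_VECS = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [0.0, 1.0, 1.0, 0.0],
    ]
)
H_MATS = np.array(
    [
        [[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 0], [0, 0, 0, 0]],
        [[0, 0, 0, 0], [0, 0, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]],
        [[0, 0, 1, 0], [0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0]],
    ],
    dtype=float,
)


def constitutive_matrix(mat: MaterialParams) -> np.ndarray:
    """Plane-strain isotropic constitutive matrix D (3x3, kPa)."""
    E, v = mat.E, mat.v
    if v >= 0.5:
        raise SingularMaterialError("v >= 0.5 gives a singular plane-strain matrix")
    f = E * (1 - v) / ((1 + v) * (1 - 2 * v))
    r = v / (1 - v)
    return f * np.array(
        [
            [1.0, r, 0.0],
            [r, 1.0, 0.0],
            [0.0, 0.0, (1 - 2 * v) / (2 * (1 - v))],
        ]
    )


def element_b_matrices(mesh: TriMesh) -> np.ndarray:
    """Per-element (4, 6) matrices mapping element dofs to g.

    Element dof order is [u1x, u1y, u2x, u2y, u3x, u3y]; rows of B follow
    the g ordering [du_X/dX, du_Y/dX, du_X/dY, du_Y/dY] with entries
    b_i/(2A) and c_i/(2A) (shape-function derivatives).
    """
    m = mesh.n_elements
    B = np.zeros((m, 4, 6))
    inv2A = 1.0 / (2.0 * mesh.area)
    for i in range(3):
        bi = mesh.b[:, i] * inv2A
        ci = mesh.c[:, i] * inv2A
        B[:, 0, 2 * i] = bi      # du_X/dX
        B[:, 1, 2 * i + 1] = bi  # du_Y/dX
        B[:, 2, 2 * i] = ci      # du_X/dY
        B[:, 3, 2 * i + 1] = ci  # du_Y/dY
    return B


def _element_dofs(mesh: TriMesh, u: NodalField) -> np.ndarray:
    """Gather nodal displacements per element, shape (m, 6)."""
    return u.values[mesh.elements].reshape(mesh.n_elements, 6)


def displacement_gradient(mesh: TriMesh, element: int, u: NodalField) -> np.ndarray:
    """Constant displacement-gradient 4-vector g of one element."""
    B = element_b_matrices(mesh)[element]
    return B @ u.values[mesh.elements[element]].ravel()


def green_strain(g: np.ndarray) -> np.ndarray:
    """Green-St.Venant strain vector(s) from displacement gradient(s).

    Accepts shape (..., 4) and returns (..., 3):
    e1 = g1 + (g1^2 + g2^2)/2, e2 = g4 + (g3^2 + g4^2)/2,
    e3 = g2 + g3 + g1 g3 + g2 g4.
    """
    g = np.asarray(g, dtype=float)
    g1, g2, g3, g4 = g[..., 0], g[..., 1], g[..., 2], g[..., 3]
    e1 = g1 + 0.5 * (g1**2 + g2**2)
    e2 = g4 + 0.5 * (g3**2 + g4**2)
    e3 = g2 + g3 + g1 * g3 + g2 * g4
    return np.stack([e1, e2, e3], axis=-1)


def element_strains(mesh: TriMesh, u: NodalField, B: np.ndarray | None = None) -> np.ndarray:
    """Green strain of every element, shape (m, 3)."""
    if B is None:
        B = element_b_matrices(mesh)
    g = np.einsum("eij,ej->ei", B, _element_dofs(mesh, u))
    return green_strain(g)


def strain_energy(mesh: TriMesh, u: NodalField, D: np.ndarray) -> float:
    """Total VK strain energy W_e = sum_el A_el * 1/2 eps^T D eps (unit thickness)."""
    eps = element_strains(mesh, u)
    return float(0.5 * np.einsum("e,em,mn,en->", mesh.area, eps, D, eps))


def elastic_force(mesh: TriMesh, u: NodalField, D: np.ndarray) -> NodalField:
    """Analytic elastic nodal forces: the exact gradient of strain_energy.

    Per element F_el = A * B^T sum_m s_m (h_m + H_m g) with s = D eps;
    assembled over elements into the global (n_nodes, 2) field.
    """
    B = element_b_matrices(mesh)
    g = np.einsum("eij,ej->ei", B, _element_dofs(mesh, u))  # (m, 4)
    eps = green_strain(g)
    s = eps @ D.T  # (m, 3) stresses
    # d eps_m / d g = h_m + H_m g  (H_m symmetric)
    deps = H_VECS[None, :, :] + np.einsum("mij,ej->emi", H_MATS, g)  # (m_el, 3, 4)
    dWdg = np.einsum("em,emi->ei", s, deps)  # (m_el, 4)
    Fel = mesh.area[:, None] * np.einsum("eij,ei->ej", B, dWdg)  # (m_el, 6)
    F = np.zeros((mesh.n_nodes, 2))
    np.add.at(F, mesh.elements.ravel(), Fel.reshape(-1, 3, 2).reshape(-1, 2))
    return NodalField(F, "elastic_force")


def linear_stiffness(mesh: TriMesh, D: np.ndarray) -> sp.csr_matrix:
    """Small-strain stiffness matrix K (2n x 2n, sparse symmetric).

    Uses the linearized strain (h_m terms only): K = sum_el A * Blin^T D Blin,
    so K u equals the small-displacement limit of the nonlinear elastic force.
    """
    B = element_b_matrices(mesh)  # (m, 4, 6)
    Blin = np.einsum("mi,eij->emj", H_VECS, B)  # (m_el, 3, 6)
    Kel = mesh.area[:, None, None] * np.einsum("emi,mn,enj->eij", Blin, D, Blin)
    dofs = np.empty((mesh.n_elements, 6), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    K = sp.coo_matrix(
        (Kel.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)
    ).tocsr()
    # symmetrize exactly against floating-point assembly asymmetry
    return (K + K.T) * 0.5
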