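"""Uniform triangular finite-element meshes over a 2D image domain.

The mesh is a regular grid of nodes spanning the pixel rectangle
``[0, width-1] x [0, height-1]`` (x = column, y = row, pixel centers at
integer coordinates), with every grid cell split into two triangles along
the lower-left-to-upper-right diagonal.  Linear (P1) shape functions are
the natural (barycentric) coordinates

    N_i(x, y) = (a_i + b_i x + c_i y) / (2 A),

with ``a_1 = x2 y3 - x3 y2``, ``b_1 = y2 - y3``, ``c_1 = x3 - x2`` and the
other coefficients by cyclic interchange of the indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriMesh",
    "NodalField",
    "OutOfDomainError",
    "OutOfElementError",
    "build_uniform_trimesh",
    "shape_values",
    "locate_element",
    "interpolate_nodal_field",
]


class OutOfDomainError(ValueError):
    """A query point lies outside the meshed rectangle."""


class OutOfElementError(ValueError):
    """A query point lies outside the requested element."""


@dataclass
class TriMesh:
    """Uniform triangular mesh with precomputed P1 geometry coefficients.

    Attributes
    ----------
    nodes : (n, 2) float array of node positions (x, y) in pixels.
    elements : (m, 3) int array of counter-clockwise node indices.
    a, b, c : (m, 3) arrays of shape-function coefficients.
    area : (m,) element areas in pixel^2.
    width, height : extent of the meshed image domain in pixels.
    nodes_per_axis : grid resolution (nodes per axis).
    """

    nodes: np.ndarray
    elements: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    area: np.ndarray
    width: int
    height: int
    nodes_per_axis: int
    spacing: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        n = self.nodes_per_axis
        self.spacing = ((self.width - 1) / (n - 1), (self.height - 1) / (n - 1))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_nodes(self, el: int) -> np.ndarray:
        """Positions of the three nodes of element ``el``, shape (3, 2)."""
        return self.nodes[self.elements[el]]

    def save_text(self, path: str | Path) -> None:
        """Write an OFF-style plain-text dump (debugging aid)."""
        lines = [f"{self.n_nodes} {self.n_elements}"]
        lines += [f"{x:.10g} {y:.10g}" for x, y in self.nodes]
        lines += [f"{i} {j} {k}" for i, j, k in self.elements]
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class NodalField:
    """One 2-vector per mesh node, ordered by node index.

    ``tag`` records the semantics: "displacement" (pixels),
    "elastic_force" or "external_force" (force units).
    """

    values: np.ndarray
    tag: str = "displacement"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("NodalField values must have shape (n_nodes, 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("NodalField values must be finite")

    @classmethod
    def zeros(cls, mesh: TriMesh, tag: str = "displacement") -> "NodalField":
        return cls(np.zeros((mesh.n_nodes, 2)), tag)


def build_uniform_trimesh(width: int, height: int, nodes_per_axis: int) -> TriMesh:
    """Build a regular ``nodes_per_axis`` x ``nodes_per_axis`` triangulated grid.

    The grid spans ``[0, width-1] x [0, height-1]``; each cell is split along
    its lower-left-to-upper-right diagonal into two counter-clockwise
    triangles, giving ``2 (n-1)^2`` elements.
    """
    n = int(nodes_per_axis)
    if n < 2:
        raise ValueError(f"nodes_per_axis must be >= 2, got {nodes_per_axis}")
    if width < 2 or height < 2:
        raise ValueError("width and height must be >= 2 pixels")

    xs = np.linspace(0.0, width - 1.0, n)
    ys = np.linspace(0.0, height - 1.0, n)
    gx, gy = np.meshgrid(xs, ys)  # row-major: node index = iy * n + ix
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    elements = np.empty((2 * (n - 1) ** 2, 3), dtype=np.int64)
    k = 0
    for iy in range(n - 1):
        for ix in range(n - 1):
            p00 = iy * n + ix
            p10 = p00 + 1
            p01 = p00 + n
            p11 = p01 + 1
            # diagonal p00 -> p11; CCW orientation in (x, y)
            elements[k] = (p00, p10, p11)
            elements[k + 1] = (p00, p11, p01)
            k += 2

    x = nodes[elements, 0]  # (m, 3)
    y = nodes[elements, 1]
    # cyclic coefficients: a_i = x_j y_k - x_k y_j, b_i = y_j - y_k, c_i = x_k - x_j
    j = [1, 2, 0]
    kk = [2, 0, 1]
    a = x[:, j] * y[:, kk] - x[:, kk] * y[:, j]
    b = y[:, j] - y[:, kk]
    c = x[:, kk] - x[:, j]
    area = 0.5 * (
        (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
        - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    )
    if np.any(area <= 0):
        raise ValueError("element orientation error: non-positive area")
    return TriMesh(nodes, elements, a, b, c, area, int(width), int(height), n)


def shape_values(mesh: TriMesh, element: int, point) -> np.ndarray:
    """P1 shape-function values (natural coordinates) of ``point`` in ``element``.

    Raises :class:`OutOfElementError` if the point is outside the element
    beyond a 1e-9 tolerance.
    """
    px, py = float(point[0]), float(point[1])
    N = (mesh.a[element] + mesh.b[element] * px + mesh.c[element] * py) / (
        2.0 * mesh.area[element]
    )
    if N.min() < -1e-9:
        raise OutOfElementError(
            f"point ({px}, {py}) outside element {element} (min N = {N.min():.3g})"
        )
    return N


def _in_domain(mesh: TriMesh, px: float, py: float, tol: float = 1e-9) -> bool:
    return (-tol <= px <= mesh.width - 1 + tol) and (-tol <= py <= mesh.height - 1 + tol)


def locate_element(mesh: TriMesh, point) -> int:
    """Return the lowest-index element containing ``point`` (ties on shared
    edges/vertices resolve to the lowest element index)."""
    px, py = float(point[0]), float(point[1])
    if not _in_domain(mesh, px, py):
        raise OutOfDomainError(f"point ({px}, {py}) outside mesh region")
    n = mesh.nodes_per_axis
    sx, sy = mesh.spacing
    cx = int(np.clip(np.floor(px / sx), 0, n - 2))
    cy = int(np.clip(np.floor(py / sy), 0, n - 2))
    # scan candidate cells around the located cell in ascending element index,
    # matching a brute-force lowest-index scan for boundary/tie points
    cand: list[int] = []
    for iy in range(max(0, cy - 1), min(n - 2, cy + 1) + 1):
        for ix in range(max(0, cx - 1), min(n - 2, cx + 1) + 1):
            base = 2 * (iy * (n - 1) + ix)
            cand += [base, base + 1]
    for el in sorted(cand):
        N = (mesh.a[el] + mesh.b[el] * px + mesh.c[el] * py) / (2.0 * mesh.area[el])
        if N.min() >= -1e-9:
            return el
    raise OutOfDomainError(f"point ({px}, {py}) not located in any candidate element")


def _locate_cells_vectorized(mesh: TriMesh, pts: np.ndarray):
    """Vectorized element assignment for interior interpolation.

    Points exactly on cell boundaries are assigned by floor convention; the
    interpolated value is identical either way by continuity.
    """
    n = mesh.nodes_per_axis
    sx, sy = mesh.spacing
    cx = np.clip(np.floor(pts[:, 0] / sx), 0, n - 2).astype(np.int64)
    cy = np.clip(np.floor(pts[:, 1] / sy), 0, n - 2).astype(np.int64)
    fx = pts[:, 0] - cx * sx
    fy = pts[:, 1] - cy * sy
    upper = fy * sx > fx * sy  # above the p00->p11 diagonal
    return 2 * (cy * (n - 1) + cx) + upper.astype(np.int64)


def interpolate_nodal_field(mesh: TriMesh, fld: NodalField, points) -> np.ndarray:
    """Interpolate a nodal 2-vector field at arbitrary points, u(x) = sum N_i u_i.

    Exact at nodes, linear over each element.  Points must lie in the mesh
    region (1e-9 tolerance); returns an (n_points, 2) array.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tol = 1e-9
    if (
        pts[:, 0].min() < -tol
        or pts[:, 1].min() < -tol
        or pts[:, 0].max() > mesh.width - 1 + tol
        or pts[:, 1].max() > mesh.height - 1 + tol
    ):
        raise OutOfDomainError("interpolation point outside mesh region")
    els = _locate_cells_vectorized(mesh, pts)
    N = (
        mesh.a[els]
        + mesh.b[els] * pts[:, 0:1]
        + mesh.c[els] * pts[:, 1:2]
    ) / (2.0 * mesh.area[els, None])
    return np.einsum("pi,pid->pd", N, fld.values[mesh.elements[els]])
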