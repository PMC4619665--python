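"""Spatially encoded mutual information (SEMI) forces and similarity metrics.

SEMI evaluates mutual information locally: around each spatial center x'
a Gaussian window G_s(x, x') of std gamma weights pixel contributions to
a Parzen joint intensity density p_s(r', m'), and the similarity is the
MI of those local densities.  The external force driving registration is
the gradient flow of this similarity with respect to the displacement:
at pixel x,

    R(x) = w(x)/N_s * [ phi_r(x,:) . L_s . dphi_m(x,:) ] * grad m_w(x),

with L_s(r', m') = 1 + log(p_s / (p_s(r') p_s(m'))), phi the Parzen
kernel responses of the reference and the warped floating intensity on a
discrete intensity grid, and grad m_w the spatial gradient of the warped
floating image.  Local densities are evaluated at mesh-node centers and
shared by the pixels nearest to each node; the force is therefore an
ascent direction of the discretized SEMI similarity.

Intensities are assumed rescaled to [0, 1] (the I/O layer guarantees
this), so beta and the bin grid are bit-depth independent.

Global similarity metrics (MSD, NC, MI, NMI) used by the evaluation
protocol live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import NodalField, TriMesh, _locate_cells_vectorized

__all__ = [
    "SemiParams",
    "UndefinedMetricError",
    "parzen_kernel",
    "spatial_weight",
    "local_joint_density",
    "semi_similarity",
    "semi_force_field",
    "assemble_external_force",
    "metric_msd",
    "metric_nc",
    "metric_mi",
    "metric_nmi",
]

_EPS = 1e-12


class UndefinedMetricError(ValueError):
    """Metric undefined for the given input (e.g. constant image)."""


@dataclass
class SemiParams:
    """SEMI metric parameters.

    d : local region diameter in pixels (default 15, the value that
        maximizes NC/NMI in the underlying study).
    gamma : spatial weighting std in pixels; default 0.25 * d.
    beta : Parzen smoothing width on the [0, 1] intensity scale
        (default 1/32, standard Parzen-MI practice).
    n_bins : intensity grid for density evaluation (default 32).
    force_weight : scalar applied when assembling nodal external forces;
        None requests auto-balancing against the elastic force scale.
    """

    d: float = 15.0
    gamma: float | None = None
    beta: float = 1.0 / 32.0
    n_bins: int = 32
    force_weight: float | None = None

    def __post_init__(self) -> None:
        if self.gamma is None:
            self.gamma = 0.25 * self.d
        if self.d <= 0 or self.gamma <= 0 or self.beta <= 0:
            raise ValueError("d, gamma and beta must be positive")
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        if self.force_weight is not None and self.force_weight <= 0:
            raise ValueError("force_weight must be positive")

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) / self.n_bins

    @property
    def bin_width(self) -> float:
        return 1.0 / self.n_bins


def parzen_kernel(y1, y2, beta: float):
    """Separable Gaussian Parzen kernel, unit integral over the plane."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    return (
        1.0
        / (2.0 * np.pi * beta**2)
        * np.exp(-(y1**2) / (2 * beta**2))
        * np.exp(-(y2**2) / (2 * beta**2))
    )


def spatial_weight(x, x_center, gamma: float):
    """Gaussian spatial encoding weight G_s(x, x') = exp(-|x-x'|^2/gamma^2)/(2 pi gamma^2)."""
    x = np.asarray(x, dtype=float)
    xc = np.asarray(x_center, dtype=float)
    d2 = np.sum((x - xc) ** 2, axis=-1)
    return np.exp(-d2 / gamma**2) / (2.0 * np.pi * gamma**2)


def _kernel_tables(img: np.ndarray, params: SemiParams, derivative: bool = False):
    """Per-pixel Parzen responses on the bin grid, normalized to unit mass.

    Returns ``phi`` of shape img.shape + (n_bins,) with rows summing to 1
    (discrete bin masses); with ``derivative`` also returns d(phi)/d(intensity)
    of the normalized responses.
    """
    c = params.bin_centers
    beta = params.beta
    y = img[..., None] - c  # (..., bins)
    raw = np.exp(-(y**2) / (2 * beta**2))
    S = raw.sum(axis=-1, keepdims=True)
    phi = raw / S
    if not derivative:
        return phi
    draw = -(y / beta**2) * raw
    dS = draw.sum(axis=-1, keepdims=True)
    dphi = (draw * S - raw * dS) / S**2
    return phi, dphi


def _window(center, half: int, shape):
    cx = int(round(float(center[0])))
    cy = int(round(float(center[1])))
    y0, y1 = max(0, cy - half), min(shape[0] - 1, cy + half)
    x0, x1 = max(0, cx - half), min(shape[1] - 1, cx + half)
    return (slice(y0, y1 + 1), slice(x0, x1 + 1)), (cx, cy)


def _gauss_window(sl, cx, cy, gamma):
    ys = np.arange(sl[0].start, sl[0].stop)
    xs = np.arange(sl[1].start, sl[1].stop)
    d2 = (ys[:, None] - cy) ** 2 + (xs[None, :] - cx) ** 2
    return np.exp(-d2 / gamma**2)


def _local_joint_mass(phi_r, phi_m, sl, cx, cy, gamma):
    """Spatially weighted joint bin-mass matrix at one center (sums to 1)."""
    w = _gauss_window(sl, cx, cy, gamma).ravel()
    nb = phi_r.shape[-1]
    wphi = phi_r[sl].reshape(-1, nb) * w[:, None]
    P = wphi.T @ phi_m[sl].reshape(-1, nb)
    return P / w.sum()


def local_joint_density(ref: np.ndarray, flt_warped: np.ndarray, center, params: SemiParams) -> np.ndarray:
    """Local Parzen joint intensity density around ``center``.

    Returns an (n_bins, n_bins) grid of density values whose sum times the
    bin area equals 1.  Degenerate (constant-intensity) regions yield a
    density concentrated at the constant value.
    """
    if ref.shape != flt_warped.shape:
        raise ValueError("images must have the same shape")
    phi_r = _kernel_tables(ref, params)
    phi_m = _kernel_tables(flt_warped, params)
    half = int(round(params.d / 2.0))
    sl, (cx, cy) = _window(center, half, ref.shape)
    P = _local_joint_mass(phi_r, phi_m, sl, cx, cy, params.gamma)
    return P / params.bin_width**2


def _mi_of_mass(P: np.ndarray) -> float:
    """MI of a joint bin-mass matrix (sums to 1)."""
    pr = P.sum(axis=1)
    pm = P.sum(axis=0)
    Pc = np.maximum(P, _EPS)
    return float(np.sum(P * (np.log(Pc) - np.log(np.maximum(np.outer(pr, pm), _EPS)))))


def _node_centers(mesh: TriMesh) -> np.ndarray:
    return np.rint(mesh.nodes).astype(int)


def semi_similarity(ref: np.ndarray, flt_warped: np.ndarray, params: SemiParams,
                    centers: np.ndarray) -> float:
    """Discrete SEMI similarity: mean local MI over the given centers (x, y)."""
    phi_r = _kernel_tables(ref, params)
    phi_m = _kernel_tables(flt_warped, params)
    half = int(round(params.d / 2.0))
    vals = []
    for cx, cy in np.atleast_2d(centers):
        sl, (cx, cy) = _window((cx, cy), half, ref.shape)
        P = _local_joint_mass(phi_r, phi_m, sl, cx, cy, params.gamma)
        vals.append(_mi_of_mass(P))
    return float(np.mean(vals))


def semi_force_field(ref: np.ndarray, flt: np.ndarray, u_dense: np.ndarray,
                     params: SemiParams, mesh: TriMesh | None = None,
                     flt_warped: np.ndarray | None = None) -> np.ndarray:
    """Dense SEMI gradient-flow force field, shape (H, W, 2), x-component first.

    ``u_dense`` is the current dense displacement (H, W, 2).  Local density
    statistics L_s are evaluated at the nodes of ``mesh`` (or at a default
    grid of spacing ~d if no mesh is given) and shared by the pixels nearest
    to each center; each pixel's contribution carries its spatial weight
    G_s relative to its center.  The returned field is an ascent direction
    of the SEMI similarity.
    """
    if ref.shape != flt.shape:
        raise ValueError("ref and flt must have the same shape")
    if flt_warped is None:
        from .pipeline import warp_image

        flt_warped = warp_image(flt, u_dense)
    H, W = ref.shape
    phi_r = _kernel_tables(ref, params)
    phi_m, dphi_m = _kernel_tables(flt_warped, params, derivative=True)
    # self-matched kernel derivative: the same contraction evaluated at the
    # reference intensity.  Subtracting it removes the finite-sample
    # histogram-gradient artifact so the force vanishes where m_w = r.
    _, dphi_r = _kernel_tables(ref, params, derivative=True)
    gy, gx = np.gradient(flt_warped)

    if mesh is not None:
        centers = _node_centers(mesh)
        nx = mesh.nodes_per_axis
        sx, sy = mesh.spacing
    else:
        step = max(4, int(round(params.d / 2)))
        xs = np.arange(0, W, step)
        ys = np.arange(0, H, step)
        nx = len(xs)
        sx, sy = float(step), float(step)
        centers = np.array([(x, y) for y in ys for x in xs])

    half = int(round(params.d / 2.0))
    nb = params.n_bins
    scal = np.zeros((H, W))
    # blocks of pixels nearest to each center (regular grid -> rectangles)
    for idx, (cx0, cy0) in enumerate(centers):
        sl, (cx, cy) = _window((cx0, cy0), half, ref.shape)
        w = _gauss_window(sl, cx, cy, params.gamma).ravel()
        wsum = w.sum()
        wphi = phi_r[sl].reshape(-1, nb) * w[:, None]
        P = (wphi.T @ phi_m[sl].reshape(-1, nb)) / wsum
        pr = P.sum(axis=1)
        pm = P.sum(axis=0)
        L = 1.0 + np.log(np.maximum(P, _EPS)) - np.log(np.maximum(np.outer(pr, pm), _EPS))
        # pixels assigned to this center (nearest-center rectangle)
        iy, ix = divmod(idx, nx)
        bx0 = 0 if ix == 0 else int(np.ceil((ix - 0.5) * sx))
        bx1 = W if ix == nx - 1 else int(np.ceil((ix + 0.5) * sx))
        by0 = 0 if iy == 0 else int(np.ceil((iy - 0.5) * sy))
        by1 = H if iy == nx - 1 else int(np.ceil((iy + 0.5) * sy))
        if bx0 >= bx1 or by0 >= by1:
            continue
        blk = (slice(by0, by1), slice(bx0, bx1))
        pR = phi_r[blk].reshape(-1, nb)
        dM = dphi_m[blk].reshape(-1, nb) - dphi_r[blk].reshape(-1, nb)
        s = ((pR @ L) * dM).sum(axis=1)
        gw = _gauss_window(blk, cx, cy, params.gamma).ravel() / wsum
        scal[blk] = (s * gw).reshape(by1 - by0, bx1 - bx0)
    out = np.empty((H, W, 2))
    out[..., 0] = scal * gx
    out[..., 1] = scal * gy
    return out


def assemble_external_force(mesh: TriMesh, field: np.ndarray,
                            force_weight: float = 1.0) -> NodalField:
    """Assemble nodal external forces R_i = w * integral of field * N_i.

    The element integral is evaluated by pixel-sum quadrature with
    trapezoidal border weights, so a uniform field f yields total nodal
    force f * meshed area * force_weight (exactly for the uniform case).
    """
    H, W = field.shape[:2]
    xs = np.arange(mesh.width, dtype=float)
    ys = np.arange(mesh.height, dtype=float)
    px, py = np.meshgrid(xs, ys)
    pts = np.column_stack([px.ravel(), py.ravel()])
    wx = np.ones(mesh.width)
    wx[0] = wx[-1] = 0.5
    wy = np.ones(mesh.height)
    wy[0] = wy[-1] = 0.5
    qw = (wy[:, None] * wx[None, :]).ravel()
    els = _locate_cells_vectorized(mesh, pts)
    N = (mesh.a[els] + mesh.b[els] * pts[:, 0:1] + mesh.c[els] * pts[:, 1:2]) / (
        2.0 * mesh.area[els, None]
    )
    f = field[: mesh.height, : mesh.width].reshape(-1, 2) * qw[:, None]
    contrib = N[:, :, None] * f[:, None, :]  # (P, 3, 2)
    R = np.zeros((mesh.n_nodes, 2))
    np.add.at(R, mesh.elements[els].ravel(), contrib.reshape(-1, 2))
    return NodalField(R * force_weight, "external_force")


# ---------------------------------------------------------------------------
# global similarity metrics


def metric_msd(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared intensity difference."""
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    return float(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2))


def metric_nc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized (Pearson) cross-correlation, in [-1, 1]."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedMetricError("NC undefined for a constant image")
    da, db = a - a.mean(), b - b.mean()
    na, nbn = np.linalg.norm(da), np.linalg.norm(db)
    return float(np.dot(da, db) / (na * nbn))


def _entropies(a, b, n_bins):
    hist, _, _ = np.histogram2d(
        np.asarray(a, float).ravel(), np.asarray(b, float).ravel(), bins=n_bins
    )
    P = hist / hist.sum()
    pr = P.sum(axis=1)
    pm = P.sum(axis=0)

    def H(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    return H(pr), H(pm), H(P.ravel())


def metric_mi(a: np.ndarray, b: np.ndarray, n_bins: int = 64) -> float:
    """Mutual information H(a) + H(b) - H(a, b) from an n_bins joint histogram."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    Ha, Hb, Hab = _entropies(a, b, n_bins)
    return Ha + Hb - Hab


def metric_nmi(a: np.ndarray, b: np.ndarray, n_bins: int = 64) -> float:
    """Normalized mutual information (H(a) + H(b)) / H(a, b), in [1, 2]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    Ha, Hb, Hab = _entropies(a, b, n_bins)
    if Hab == 0 or Ha == 0 or Hb == 0:
        raise UndefinedMetricError("NMI undefined for a constant image")
    return (Ha + Hb) / Hab
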