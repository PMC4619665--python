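"""Hierarchical global-to-local registration driver.

The pipeline mirrors the global-to-local strategy: an optional global
stage maximizes mutual information over a rigid or affine transform
(derivative-free Powell search on a 3-level image pyramid); then a
coarse-to-fine sequence of triangular mesh levels relaxes the chosen
finite-element model (LFEM / DFEM / NFEM) against the SEMI gradient-flow
external force, each level starting from the previous level's nodal
displacements.  The final dense displacement composes the FEM field with
the global transform so that a reference point x maps to
x + u_total(x) in the floating image.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy import ndimage, optimize

from .dynamics import KPA_TO_BASE, lfem_solve, relax_to_equilibrium
from .elasticity import MaterialParams, constitutive_matrix, elastic_force
from .mesh import NodalField, TriMesh, build_uniform_trimesh, interpolate_nodal_field
from .semi import (
    SemiParams,
    UndefinedMetricError,
    assemble_external_force,
    metric_mi,
    metric_msd,
    metric_nc,
    metric_nmi,
    semi_force_field,
)

__all__ = [
    "LevelConfig",
    "RegistrationConfig",
    "RegistrationResult",
    "warp_image",
    "global_register",
    "hierarchical_register",
    "dense_from_nodal",
]


@dataclass
class LevelConfig:
    """One pyramid level: mesh resolution and smoothing/relaxation settings.

    ``semi_d`` optionally overrides the SEMI region diameter for this
    level (coarse levels gain capture range from a wider window; the
    spatial std scales along as gamma = 0.25 d).
    """

    nodes_per_axis: int
    gaussian_sigma: float = 1.0
    max_steps: int = 500
    tol: float = 1e-3
    semi_d: float | None = None


@dataclass
class RegistrationConfig:
    """Full registration configuration (all defaults overridable)."""

    model: Literal["LFEM", "DFEM", "NFEM"] = "NFEM"
    levels: list[LevelConfig] = dc_field(
        default_factory=lambda: [LevelConfig(32, 2.0), LevelConfig(64, 1.0)]
    )
    material: MaterialParams = dc_field(default_factory=MaterialParams)
    semi: SemiParams = dc_field(default_factory=SemiParams)
    global_stage: Literal["none", "rigid", "affine"] = "affine"
    seed: int = 0
    refresh_interval: int = 10

    def __post_init__(self) -> None:
        if self.model not in ("LFEM", "DFEM", "NFEM"):
            raise ValueError(f"unknown model {self.model!r}")
        npa = [lv.nodes_per_axis for lv in self.levels]
        if any(b <= a for a, b in zip(npa, npa[1:])):
            raise ValueError("levels must be ordered coarse to fine (increasing nodes)")


@dataclass
class RegistrationResult:
    """Registration output: dense field, warped image and diagnostics."""

    dense_u: np.ndarray
    warped: np.ndarray
    level_trace: list[dict]
    global_params: dict | None
    metrics_before: dict
    metrics_after: dict


def warp_image(flt: np.ndarray, u_dense: np.ndarray) -> np.ndarray:
    """Backward-map resampling: out(x) = flt(x + u(x)), bilinear, border clamp."""
    H, W = flt.shape
    if u_dense.shape[:2] != (H, W):
        raise ValueError("field and image shapes do not match")
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    return ndimage.map_coordinates(
        np.asarray(flt, float),
        [Y + u_dense[..., 1], X + u_dense[..., 0]],
        order=1,
        mode="nearest",
    )


def _apply_transform(flt: np.ndarray, M: np.ndarray, t: np.ndarray,
                     center: np.ndarray) -> np.ndarray:
    """Resample: out(x) = flt(M (x - c) + c + t), bilinear."""
    H, W = flt.shape
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    dx = X - center[0]
    dy = Y - center[1]
    Xs = M[0, 0] * dx + M[0, 1] * dy + center[0] + t[0]
    Ys = M[1, 0] * dx + M[1, 1] * dy + center[1] + t[1]
    return ndimage.map_coordinates(np.asarray(flt, float), [Ys, Xs], order=1, mode="nearest")


def _params_to_Mt(p: np.ndarray, mode: str):
    if mode == "rigid":
        th = p[2]
        M = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = np.array([p[0], p[1]])
    else:
        M = np.array([[1.0 + p[0], p[1]], [p[2], 1.0 + p[3]]])
        t = np.array([p[4], p[5]])
    return M, t


def global_register(ref: np.ndarray, flt: np.ndarray,
                    mode: Literal["rigid", "affine"] = "affine",
                    n_bins: int = 64) -> tuple[dict, np.ndarray]:
    """MI-maximizing global stage (derivative-free Powell, 3-level pyramid).

    Returns (params, resampled floating image); params hold the backward
    map out(x) = flt(M (x - c) + c + t).  The returned MI is never below
    the MI at the identity.
    """
    if ref.shape != flt.shape:
        raise ValueError("images must have the same shape")
    try:
        mi0 = metric_mi(ref, flt, n_bins)
    except UndefinedMetricError:
        raise
    if np.ptp(ref) == 0 or np.ptp(flt) == 0:
        raise UndefinedMetricError("global registration undefined for constant images")
    H, W = ref.shape
    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    nparam = 3 if mode == "rigid" else 6
    p = np.zeros(nparam)
    for f in (4, 2, 1):
        if min(H, W) // f < 32 and f > 1:
            continue
        r = ndimage.gaussian_filter(ref, f / 2.0)[::f, ::f] if f > 1 else ref
        m = ndimage.gaussian_filter(flt, f / 2.0)[::f, ::f] if f > 1 else flt
        c = center / f

        def neg_mi(q):
            M, t = _params_to_Mt(q, mode)
            tt = t / f
            return -metric_mi(r, _apply_transform(m, M, tt, c), n_bins)

        res = optimize.minimize(
            neg_mi, p, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": 40 * nparam},
        )
        p = res.x
    M, t = _params_to_Mt(p, mode)
    out = _apply_transform(flt, M, t, center)
    mi1 = metric_mi(ref, out, n_bins)
    if mi1 < mi0:  # never worse than identity
        M, t = np.eye(2), np.zeros(2)
        out = np.asarray(flt, float).copy()
        mi1 = mi0
    params = {"mode": mode, "matrix": M, "t": t, "center": center,
              "mi_before": mi0, "mi_after": mi1}
    return params, out


def dense_from_nodal(mesh: TriMesh, u: NodalField, shape: tuple[int, int]) -> np.ndarray:
    """Interpolate a nodal displacement field to every pixel, (H, W, 2)."""
    H, W = shape
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    pts = np.column_stack([np.clip(X.ravel(), 0, mesh.width - 1),
                           np.clip(Y.ravel(), 0, mesh.height - 1)])
    return interpolate_nodal_field(mesh, u, pts).reshape(H, W, 2)


def _auto_force_weight(mesh: TriMesh, D: np.ndarray, R_raw: NodalField,
                       ratio: float = 10.0) -> float:
    """Scale the external force so its initial max nodal magnitude equals
    ``ratio`` times the elastic force of a 1-pixel test displacement."""
    u_test = NodalField.zeros(mesh)
    i = (mesh.nodes_per_axis // 2) * mesh.nodes_per_axis + mesh.nodes_per_axis // 2
    u_test.values[i, 0] = 1.0
    f_el = np.abs(elastic_force(mesh, u_test, D).values).max() * KPA_TO_BASE
    r_max = np.linalg.norm(R_raw.values, axis=1).max()
    if r_max <= 0:
        return 1.0
    return ratio * f_el / r_max


def _metrics(ref, img) -> dict:
    return {
        "MSD": metric_msd(ref, img),
        "NC": metric_nc(ref, img),
        "NMI": metric_nmi(ref, img),
    }


def hierarchical_register(ref: np.ndarray, flt: np.ndarray,
                          config: RegistrationConfig) -> RegistrationResult:
    """Run the full global-to-local registration and return the dense field.

    Deterministic: identical inputs, config and seed give bit-identical
    output fields.
    """
    ref = np.asarray(ref, float)
    flt = np.asarray(flt, float)
    if ref.shape != flt.shape:
        raise ValueError("images must have the same shape")
    H, W = ref.shape
    metrics_before = _metrics(ref, flt)

    gparams = None
    flt_g = flt
    if config.global_stage != "none":
        gparams, flt_g = global_register(ref, flt, config.global_stage,
                                         config.semi.n_bins * 2)

    D = constitutive_matrix(config.material)
    mesh_prev: TriMesh | None = None
    u_nodal: NodalField | None = None
    trace: list[dict] = []
    for li, lv in enumerate(config.levels):
        ref_s = ndimage.gaussian_filter(ref, lv.gaussian_sigma)
        flt_s = ndimage.gaussian_filter(flt_g, lv.gaussian_sigma)
        mesh = build_uniform_trimesh(W, H, lv.nodes_per_axis)
        if u_nodal is None:
            u0 = NodalField.zeros(mesh)
        else:
            u0 = NodalField(interpolate_nodal_field(mesh_prev, u_nodal, mesh.nodes))

        if lv.semi_d is None:
            semi_lv = config.semi
        else:
            semi_lv = SemiParams(d=lv.semi_d, beta=config.semi.beta,
                                 n_bins=config.semi.n_bins,
                                 force_weight=config.semi.force_weight)

        def provider(u_nf: NodalField, _mesh=mesh, _semi=semi_lv, _w=[None]) -> NodalField:
            u_dense = dense_from_nodal(_mesh, u_nf, (H, W))
            fld = semi_force_field(ref_s, flt_s, u_dense, _semi, mesh=_mesh)
            R_raw = assemble_external_force(_mesh, fld, 1.0)
            if _w[0] is None:
                _w[0] = (config.semi.force_weight
                         if config.semi.force_weight is not None
                         else _auto_force_weight(_mesh, D, R_raw))
            return NodalField(R_raw.values * _w[0], "external_force")

        pre = _metrics(ref, warp_image(flt_g, dense_from_nodal(mesh, u0, (H, W))))
        if config.model == "LFEM":
            u_nodal = _lfem_relax(mesh, u0, D, provider, lv)
        else:
            u_nodal = relax_to_equilibrium(
                mesh, u0, config.material, D, provider, config.model,
                max_steps=lv.max_steps, tol=lv.tol,
                refresh_interval=config.refresh_interval,
            )
        post = _metrics(ref, warp_image(flt_g, dense_from_nodal(mesh, u_nodal, (H, W))))
        trace.append({"level": li, "nodes_per_axis": lv.nodes_per_axis,
                      "before": pre, "after": post})
        mesh_prev = mesh

    u_fem = dense_from_nodal(mesh_prev, u_nodal, (H, W))
    u_total = _compose_with_global(u_fem, gparams, (H, W))
    warped = warp_image(flt, u_total)
    return RegistrationResult(u_total, warped, trace, gparams,
                              metrics_before, _metrics(ref, warped))


def _lfem_relax(mesh: TriMesh, u0: NodalField, D, provider, lv: LevelConfig,
                max_outer: int = 30, relax: float = 0.5) -> NodalField:
    """Fixed-point iteration of static solves with force refresh (LFEM).

    The net force resultant is projected off the translation nullspace
    before each solve, and the per-iteration update is trust-region
    limited to half the node spacing (the static solution of the raw
    balanced force field would otherwise overshoot by orders of
    magnitude and never fixed-point).
    """
    u = NodalField(u0.values.copy())
    step_cap = 0.5 * min(mesh.spacing)
    for _ in range(max_outer):
        R = provider(u)
        Rv = R.values - R.values.mean(axis=0, keepdims=True)
        u_new = lfem_solve(mesh, D, NodalField(Rv, "external_force"))
        du = relax * (u_new.values - u.values)
        m = np.abs(du).max()
        if m > step_cap:
            du *= step_cap / m
        u = NodalField(u.values + du)
        if np.abs(du).max() < lv.tol:
            break
    return u


def _compose_with_global(u_fem: np.ndarray, gparams: dict | None,
                         shape: tuple[int, int]) -> np.ndarray:
    """Total field: x -> M(x + u_fem(x) - c) + c + t - x."""
    if gparams is None:
        return u_fem
    H, W = shape
    M, t, c = gparams["matrix"], gparams["t"], gparams["center"]
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    px = X + u_fem[..., 0] - c[0]
    py = Y + u_fem[..., 1] - c[1]
    out = np.empty_like(u_fem)
    out[..., 0] = M[0, 0] * px + M[0, 1] * py + c[0] + t[0] - X
    out[..., 1] = M[1, 0] * px + M[1, 1] * py + c[1] + t[1] - Y
    return out
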