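"""Synthetic deformation experiments and the evaluation protocol.

The generator emulates the evaluation inputs of the registration study:
a smooth multi-structure grayscale phantom (standing in for clinical CT
slices, which are not distributable), warped through a known smooth
displacement field — cubic B-spline fields for the "small"/"large"
categories and superposed Gaussian bumps plus a mild affine part for the
"nonuniform" category — with 40 foreground landmarks carried through the
field exactly.  A deformation is "large" when the local displacement
exceeds 15 pixels somewhere.

The stored ground-truth field is the forward reference-to-floating
correspondence: a reference point p corresponds to p + field(p) in the
floating image.  The floating image is produced by resampling the
reference through the fixed-point inverse of that field, so that perfect
registration recovers the forward field and the landmark invariant
landmarks_flt = landmarks_ref + field(landmarks_ref) holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Literal

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

from .pipeline import RegistrationResult, warp_image
from .semi import metric_msd, metric_nc, metric_nmi

__all__ = [
    "DeformationExperiment",
    "DegenerateTestError",
    "SamplingError",
    "make_phantom",
    "make_bspline_field",
    "make_nonuniform_field",
    "invert_field",
    "sample_landmarks",
    "make_experiment",
    "evaluate_registration",
    "paired_t_test",
]


class DegenerateTestError(ValueError):
    """Paired t-test undefined (zero variance of the differences)."""


class SamplingError(RuntimeError):
    """Foreground region too small for the requested number of landmarks."""


@dataclass
class DeformationExperiment:
    """One synthetic evaluation unit: phantom, known field, landmarks."""

    reference: np.ndarray
    field: np.ndarray  # forward ref->flt correspondence, (H, W, 2), pixels
    floating: np.ndarray
    landmarks_ref: np.ndarray  # (n, 2) positions (x, y)
    landmarks_flt: np.ndarray
    category: Literal["small", "large", "nonuniform"]
    seed: int
    meta: dict = dc_field(default_factory=dict)


def make_phantom(width: int, height: int, seed: int) -> np.ndarray:
    """Smooth multi-structure phantom in [0, 1], reproducible from seed.

    Overlapping soft elliptical blobs inside a body-like outline, a bright
    rib-like arc, and mild smooth texture noise give non-trivial gradients
    over most of the foreground.
    """
    if min(width, height) < 64:
        raise ValueError("phantom size must be >= 64")
    rng = np.random.default_rng(seed)
    Y, X = np.mgrid[0:height, 0:width].astype(float)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    img = np.zeros((height, width))

    # body: large soft ellipse
    rx, ry = 0.38 * width, 0.40 * height
    body = np.exp(-(((X - cx) / rx) ** 4 + ((Y - cy) / ry) ** 4))
    img += 0.55 * body

    # internal soft-tissue blobs
    for _ in range(rng.integers(6, 10)):
        bx = cx + rng.uniform(-0.25, 0.25) * width
        by = cy + rng.uniform(-0.25, 0.25) * height
        sx = rng.uniform(0.04, 0.14) * width
        sy = rng.uniform(0.04, 0.14) * height
        th = rng.uniform(0, np.pi)
        dx, dy = X - bx, Y - by
        rxp = dx * np.cos(th) + dy * np.sin(th)
        ryp = -dx * np.sin(th) + dy * np.cos(th)
        amp = rng.uniform(-0.25, 0.6)
        img += amp * np.exp(-0.5 * ((rxp / sx) ** 2 + (ryp / sy) ** 2))

    # bright rib-like arc: band at fixed radius over a limited angle
    rad = rng.uniform(0.28, 0.34) * min(width, height)
    r = np.hypot(X - cx, Y - cy)
    ang = np.arctan2(Y - cy, X - cx)
    a0 = rng.uniform(-np.pi, np.pi)
    dang = np.angle(np.exp(1j * (ang - a0)))
    arc = np.exp(-0.5 * ((r - rad) / (0.015 * min(width, height))) ** 2)
    arc *= np.exp(-0.5 * (dang / 1.1) ** 2)
    img += 0.8 * arc * body

    # fine-scale smooth texture over the whole body, emulating the
    # granular tissue texture of CT slices; this is what makes the local
    # deformation observable away from structure boundaries
    tex = ndimage.gaussian_filter(rng.standard_normal((height, width)), 1.5)
    img += 0.15 * (tex / np.abs(tex).max()) * (body > 0.05)
    img *= body > 0.05  # clean background
    img -= img.min()
    img /= img.max()
    return img


def _bspline_component(coeff: np.ndarray, shape: tuple[int, int],
                       spacing: float) -> np.ndarray:
    """Evaluate a cubic B-spline surface from a coefficient grid.

    ``coeff`` lives on a grid with origin at -spacing (one knot of margin);
    map_coordinates with prefilter=False treats the input as B-spline
    coefficients.
    """
    H, W = shape
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    gy = Y / spacing + 1.0
    gx = X / spacing + 1.0
    return ndimage.map_coordinates(coeff, [gy, gx], order=3, mode="constant",
                                   prefilter=False)


def make_bspline_field(width: int, height: int, control_spacing: float = 32.0,
                       max_disp: float = 6.0, seed: int = 0) -> np.ndarray:
    """Random cubic B-spline displacement field, max magnitude = max_disp.

    C2-smooth by construction; a C2 taper window zeroes the field on a
    border margin of half a control spacing and ramps to 1 within one more
    spacing.  The field is rescaled so the maximum displacement magnitude
    equals ``max_disp`` exactly.
    """
    if max_disp < 0:
        raise ValueError("max_disp must be nonnegative")
    rng = np.random.default_rng(seed)
    ncx = int(np.ceil((width - 1) / control_spacing)) + 5
    ncy = int(np.ceil((height - 1) / control_spacing)) + 5
    field = np.zeros((height, width, 2))
    if max_disp == 0:
        return field
    for comp in range(2):
        coeff = rng.standard_normal((ncy, ncx))
        field[..., comp] = _bspline_component(coeff, (height, width), control_spacing)
    field *= (_border_window(width, control_spacing)[None, :, None]
              * _border_window(height, control_spacing)[:, None, None])
    peak = np.linalg.norm(field, axis=-1).max()
    if peak == 0:
        return field
    field *= max_disp / peak
    return field


def _border_window(n: int, spacing: float) -> np.ndarray:
    """C2 taper: exactly 0 within spacing/2 of the border, 1 beyond 1.5 spacing
    (quintic smoothstep ramp in between)."""
    x = np.arange(n, dtype=float)
    d = np.minimum(x, n - 1 - x)
    t = np.clip((d - 0.5 * spacing) / spacing, 0.0, 1.0)
    return t**3 * (10.0 - 15.0 * t + 6.0 * t**2)


def make_nonuniform_field(width: int, height: int, seed: int = 0,
                          n_bumps: tuple[int, int] = (3, 6),
                          affine_shift: float = 2.0) -> np.ndarray:
    """Non-uniform field: localized Gaussian bumps of disparate severity
    plus a mild global affine component."""
    rng = np.random.default_rng(seed)
    Y, X = np.mgrid[0:height, 0:width].astype(float)
    field = np.zeros((height, width, 2))
    k = int(rng.integers(n_bumps[0], n_bumps[1] + 1))
    # amplitudes scale with each bump's radius (cap |grad u| ~ 0.8 so the
    # total map stays diffeomorphic) while spanning >= 2x in severity
    rel = np.geomspace(0.3, 1.3, k)
    rng.shuffle(rel)
    for r_amp in rel:
        bx = rng.uniform(0.2, 0.8) * width
        by = rng.uniform(0.2, 0.8) * height
        sig = rng.uniform(0.08, 0.14) * min(width, height)
        amp = r_amp * sig
        th = rng.uniform(0, 2 * np.pi)
        g = np.exp(-0.5 * (((X - bx) ** 2 + (Y - by) ** 2) / sig**2))
        field[..., 0] += amp * np.cos(th) * g
        field[..., 1] += amp * np.sin(th) * g
    # mild affine part: small rotation/scale about center plus a shift
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    th = rng.uniform(-0.01, 0.01)
    s = rng.uniform(-0.01, 0.01)
    tx, ty = rng.uniform(-affine_shift, affine_shift, size=2)
    dx, dy = X - cx, Y - cy
    field[..., 0] += (np.cos(th) * (1 + s) - 1) * dx - np.sin(th) * (1 + s) * dy + tx
    field[..., 1] += np.sin(th) * (1 + s) * dx + (np.cos(th) * (1 + s) - 1) * dy + ty
    return field


def invert_field(fwd: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Fixed-point inverse displacement: h with h(y) = -fwd(y + h(y)).

    Backward-warping an image through ``h`` realizes the forward
    correspondence ``fwd`` (for smooth fields with |grad fwd| < 1).
    """
    H, W = fwd.shape[:2]
    Y, X = np.mgrid[0:H, 0:W].astype(float)
    h = -fwd.copy()
    for _ in range(n_iter):
        xs = np.clip(X + h[..., 0], 0, W - 1)
        ys = np.clip(Y + h[..., 1], 0, H - 1)
        fx = ndimage.map_coordinates(fwd[..., 0], [ys, xs], order=1, mode="nearest")
        fy = ndimage.map_coordinates(fwd[..., 1], [ys, xs], order=1, mode="nearest")
        h[..., 0] = -fx
        h[..., 1] = -fy
    return h


def foreground_mask(image: np.ndarray, erode: int = 5) -> np.ndarray:
    """Otsu threshold, largest connected component, ``erode``-px erosion
    and the same margin off the image border."""
    th = threshold_otsu(image)
    mask = image > th
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    if erode > 0:
        mask = ndimage.binary_erosion(mask, iterations=erode)
    border = np.zeros_like(mask)
    border[erode:-erode or None, erode:-erode or None] = True
    return mask & border


def sample_landmarks(image: np.ndarray, n: int = 40, seed: int = 0,
                     mask: np.ndarray | None = None) -> np.ndarray:
    """Sample n distinct foreground positions (x, y), reproducible from seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mask is None:
        mask = foreground_mask(image)
    ys, xs = np.nonzero(mask)
    if len(xs) < n:
        raise SamplingError(f"foreground has {len(xs)} pixels, need {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(xs), size=n, replace=False)
    return np.column_stack([xs[idx], ys[idx]]).astype(float)


def make_experiment(category: Literal["small", "large", "nonuniform"],
                    seed: int, size: int = 256, n_landmarks: int = 40,
                    control_spacing: float | None = None) -> DeformationExperiment:
    """Build one seeded experiment of the given deformation category.

    Categories follow the evaluation protocol: "small" is a B-spline field
    of ~6 px peak displacement, "large" a B-spline field whose local
    displacement exceeds 15 px (peak 18 px), "nonuniform" a superposition
    of Gaussian bumps with a mild affine part.
    """
    ref = make_phantom(size, size, seed)
    if category == "small":
        # ~6 px peak over size/8 control spacing keeps |grad u| ~ 0.4
        spacing = control_spacing if control_spacing is not None else size / 8.0
        fwd = make_bspline_field(size, size, spacing, 6.0, seed + 1)
    elif category == "large":
        # wider spacing keeps the 18 px field diffeomorphic (det J > 0)
        spacing = control_spacing if control_spacing is not None else size / 4.0
        fwd = make_bspline_field(size, size, spacing, 18.0, seed + 1)
    elif category == "nonuniform":
        fwd = make_nonuniform_field(size, size, seed + 1)
    else:
        raise ValueError(f"unknown category {category!r}")
    floating = warp_image(ref, invert_field(fwd))
    lm_ref = sample_landmarks(ref, n_landmarks, seed + 2)
    disp = _sample_field(fwd, lm_ref)
    lm_flt = lm_ref + disp
    return DeformationExperiment(ref, fwd, floating, lm_ref, lm_flt, category, seed,
                                 meta={"max_disp": float(np.linalg.norm(fwd, axis=-1).max())})


def _sample_field(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear samples of a dense (H, W, 2) field at (x, y) points."""
    ux = ndimage.map_coordinates(field[..., 0], [pts[:, 1], pts[:, 0]], order=1,
                                 mode="nearest")
    uy = ndimage.map_coordinates(field[..., 1], [pts[:, 1], pts[:, 0]], order=1,
                                 mode="nearest")
    return np.column_stack([ux, uy])


def evaluate_registration(experiment: DeformationExperiment,
                          result: RegistrationResult) -> dict:
    """Landmark distance errors and global metrics for one registration run.

    Landmarks are mapped through the recovered field (p -> p + u(p)) and
    compared per-axis with the ground-truth floating positions; metrics
    are computed before (reference vs floating) and after (reference vs
    warped) registration.  The report round-trips through JSON.
    """
    mapped = experiment.landmarks_ref + _sample_field(result.dense_u,
                                                      experiment.landmarks_ref)
    err = np.abs(mapped - experiment.landmarks_flt)
    report = {
        "category": experiment.category,
        "seed": int(experiment.seed),
        "n_landmarks": int(len(err)),
        "mean_x": float(err[:, 0].mean()),
        "mean_y": float(err[:, 1].mean()),
        "max_x": float(err[:, 0].max()),
        "max_y": float(err[:, 1].max()),
        "mean_euclidean": float(np.linalg.norm(err, axis=1).mean()),
        "before": {
            "MSD": metric_msd(experiment.reference, experiment.floating),
            "NC": metric_nc(experiment.reference, experiment.floating),
            "NMI": metric_nmi(experiment.reference, experiment.floating),
        },
        "after": {
            "MSD": metric_msd(experiment.reference, result.warped),
            "NC": metric_nc(experiment.reference, result.warped),
            "NMI": metric_nmi(experiment.reference, result.warped),
        },
    }
    json.dumps(report)  # guarantee serializability
    return report


def paired_t_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided paired Student t-test; returns (t, p).

    Raises :class:`DegenerateTestError` when the differences have zero
    variance (including identical samples).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D samples of length >= 3")
    d = a - b
    if np.allclose(d, d[0]):
        raise DegenerateTestError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
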