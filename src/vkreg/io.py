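"""Image/field readers and writers and configuration parsing.

Images are rescaled to [0, 1] on read (the original range and dtype are
kept in the metadata so writing inverts the rescale); all metric and
force parameters are therefore bit-depth independent.  Displacement
fields travel as 2-component MHD/MHA rasters with unit spacing,
x-component first.  Configs are TOML (or JSON) files mirroring
:class:`~vkreg.pipeline.RegistrationConfig`; missing keys take the
package defaults (E=100 kPa, v=0.45, rho=1000, alpha=5, dt=0.004,
d=15, gamma=3.75).
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .elasticity import MaterialParams
from .pipeline import LevelConfig, RegistrationConfig
from .semi import SemiParams

__all__ = [
    "FormatError",
    "ConfigError",
    "ImageMeta",
    "read_image",
    "write_image",
    "read_field",
    "write_field",
    "load_config",
    "config_to_dict",
]

logger = logging.getLogger("vkreg")


class FormatError(ValueError):
    """Unsupported or malformed file format."""


class ConfigError(ValueError):
    """Invalid configuration value, with the offending key in the message."""


@dataclass
class ImageMeta:
    """Original intensity range/dtype so writes can invert the rescale."""

    vmin: float
    vmax: float
    dtype: str
    source: str = ""
    extra: dict = dc_field(default_factory=dict)


_RASTER_EXT = {".png", ".tif", ".tiff"}
_NIFTI_EXT = {".nii", ".gz"}


def _rescale(arr: np.ndarray, source: str) -> tuple[np.ndarray, ImageMeta]:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise FormatError(f"multi-channel image not supported: {source}")
    meta = ImageMeta(float(arr.min()), float(arr.max()), str(arr.dtype), source)
    a = arr.astype(float)
    if meta.vmax > meta.vmin:
        a = (a - meta.vmin) / (meta.vmax - meta.vmin)
    else:
        a = np.zeros_like(a)
    return a, meta


def read_image(path: str | Path) -> tuple[np.ndarray, ImageMeta]:
    """Read a 2D grayscale image, rescaled to [0, 1].

    PNG/TIFF (8/16-bit) and NIfTI are supported; for a NIfTI volume the
    first slice along the last axis is extracted with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _RASTER_EXT:
        import imageio.v3 as iio

        return _rescale(iio.imread(path), str(path))
    if suffix in _NIFTI_EXT or path.name.lower().endswith(".nii.gz"):
        import nibabel as nib

        vol = np.asanyarray(nib.load(path).dataobj)
        if vol.ndim > 2:
            logger.warning("NIfTI volume %s has shape %s; extracting slice 0",
                           path, vol.shape)
            while vol.ndim > 2:
                vol = vol[..., 0]
        return _rescale(vol, str(path))
    raise FormatError(f"unsupported image extension {path.suffix!r}")


def write_image(image: np.ndarray, path: str | Path,
                meta: ImageMeta | None = None) -> None:
    """Write a [0, 1] image, inverting the read rescale when meta is given."""
    path = Path(path)
    suffix = path.suffix.lower()
    a = np.asarray(image, float)
    if meta is not None and meta.vmax > meta.vmin:
        a = a * (meta.vmax - meta.vmin) + meta.vmin
        out = a.astype(meta.dtype)
    else:
        out = np.clip(a * 65535.0, 0, 65535).astype(np.uint16) \
            if suffix in {".tif", ".tiff"} else \
            np.clip(a * 255.0, 0, 255).astype(np.uint8)
    if suffix in _RASTER_EXT:
        import imageio.v3 as iio

        iio.imwrite(path, out)
        return
    if suffix in _NIFTI_EXT or path.name.lower().endswith(".nii.gz"):
        import nibabel as nib

        nib.save(nib.Nifti1Image(out, np.eye(4)), path)
        return
    raise FormatError(f"unsupported image extension {path.suffix!r}")


def write_field(field: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 2) displacement field as 2-component MHD/MHA,
    x-component first, unit element spacing, 32-bit floats."""
    import SimpleITK as sitk

    field = np.asarray(field, np.float32)
    if field.ndim != 3 or field.shape[-1] != 2:
        raise FormatError("field must have shape (H, W, 2)")
    img = sitk.GetImageFromArray(field, isVector=True)
    img.SetSpacing((1.0, 1.0))
    sitk.WriteImage(img, str(path))


def read_field(path: str | Path) -> np.ndarray:
    """Read a 2-component MHD/MHA displacement field, (H, W, 2) float64."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3 or arr.shape[-1] != 2:
        raise FormatError(
            f"expected a 2-component field, got shape {arr.shape} in {path}"
        )
    return arr.astype(float)


# ---------------------------------------------------------------------------
# configuration

_MATERIAL_KEYS = {"E", "v", "rho", "alpha", "dt"}
_SEMI_KEYS = {"d", "gamma", "beta", "n_bins", "force_weight"}
_TOP_KEYS = {"model", "global_stage", "seed", "refresh_interval",
             "levels", "material", "semi"}


def load_config(path: str | Path | None = None) -> RegistrationConfig:
    """Load a TOML (or JSON) registration config; missing keys take defaults.

    Unknown keys produce a warning, not an error; type-invalid values raise
    :class:`ConfigError` naming the key.
    """
    raw: dict = {}
    if path is not None:
        p = Path(path)
        text = p.read_text()
        if p.suffix.lower() == ".json":
            raw = json.loads(text) if text.strip() else {}
        else:
            raw = tomllib.loads(text)
    return config_from_dict(raw)


def _build(section: str, cls, raw: dict, known: set):
    kwargs = {}
    for k, val in raw.items():
        if k not in known:
            logger.warning("ignoring unknown config key %s.%s", section, k)
            continue
        kwargs[k] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in [{section}]: {exc}") from exc


def config_from_dict(raw: dict) -> RegistrationConfig:
    for k in raw:
        if k not in _TOP_KEYS:
            logger.warning("ignoring unknown config key %s", k)
    material = _build("material", MaterialParams, raw.get("material", {}), _MATERIAL_KEYS)
    semi = _build("semi", SemiParams, raw.get("semi", {}), _SEMI_KEYS)
    levels_raw = raw.get("levels")
    if levels_raw is None:
        levels = [LevelConfig(32, 2.0), LevelConfig(64, 1.0)]
    else:
        levels = [
            _build(f"levels[{i}]", LevelConfig, lv,
                   {"nodes_per_axis", "gaussian_sigma", "max_steps", "tol"})
            for i, lv in enumerate(levels_raw)
        ]
    kwargs = {k: raw[k] for k in ("model", "global_stage", "seed", "refresh_interval")
              if k in raw}
    try:
        return RegistrationConfig(levels=levels, material=material, semi=semi, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: RegistrationConfig) -> dict:
    """Fully resolved config as a JSON-serializable dict (run provenance)."""
    return {
        "model": config.model,
        "global_stage": config.global_stage,
        "seed": config.seed,
        "refresh_interval": config.refresh_interval,
        "material": {k: getattr(config.material, k) for k in _MATERIAL_KEYS},
        "semi": {k: getattr(config.semi, k) for k in _SEMI_KEYS},
        "levels": [
            {"nodes_per_axis": lv.nodes_per_axis, "gaussian_sigma": lv.gaussian_sigma,
             "max_steps": lv.max_steps, "tol": lv.tol}
            for lv in config.levels
        ],
    }
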