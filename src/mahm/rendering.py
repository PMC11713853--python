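"""Display rendering: 8-bit channel scaling, merged RGB eigenvalue maps,
eigenvector maps and colormapped lambda_r overlays.

Rendering is a display-only path: it consumes quantitative maps and never
modifies them.  Eigenvalue channels are scaled linearly from 0 to the
median in-mask eigenvalue (so the bulk of tissue sits mid-range and bright
outliers clip at 255); eigenvector components, being unit-normalized, are
scaled from -1 to 1; each eigenvalue channel is scaled by its own median.
The merged map assigns red, green and blue to the first, second and third
eigenvalue channels.  Rounding is half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from matplotlib import colormaps

__all__ = [
    "DisplayScaling",
    "scale_to_8bit",
    "merge_rgb",
    "overlay",
    "colorize",
    "eigenvalue_scaling",
    "eigenvector_scaling",
]

#: Rainbow colormap used for lambda_r maps (a fixed, perceptually ordered
#: blue-to-red rainbow).
LAMBDA_R_CMAP = "turbo"


@dataclass(frozen=True)
class DisplayScaling:
    """Linear 8-bit display window: vmin -> 0, vmax -> 255, clamped."""

    vmin: float
    vmax: float
    mode: str = "linear"

    def __post_init__(self) -> None:
        if not self.vmax > self.vmin:
            raise ValueError(f"vmax {self.vmax} must exceed vmin {self.vmin}")


def eigenvalue_scaling(
    values: np.ndarray, mask: Optional[np.ndarray] = None
) -> DisplayScaling:
    """Eigenvalue display window: 0 to the median of in-mask values.

    The mask should delineate the organ of interest (the valid-data mask by
    default); the median keeps typical tissue mid-scale.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    sel = values[np.asarray(mask, bool) & np.isfinite(values)]
    if sel.size == 0:
        raise ValueError("mask selects no finite values for eigenvalue scaling")
    med = float(np.median(sel))
    if med <= 0:
        raise ValueError(f"in-mask median {med} is not positive")
    return DisplayScaling(0.0, med, "eigenvalue")


def eigenvector_scaling() -> DisplayScaling:
    """Eigenvector display window: components span [-1, 1]."""
    return DisplayScaling(-1.0, 1.0, "eigenvector")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def scale_to_8bit(values: np.ndarray, scaling: DisplayScaling) -> np.ndarray:
    """Linearly map values to 0..255 with clamping; NaN maps to 0."""
    values = np.asarray(values, dtype=float)
    span = scaling.vmax - scaling.vmin
    scaled = 255.0 * (values - scaling.vmin) / span
    scaled = np.where(np.isfinite(scaled), scaled, 0.0)
    return np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)


def merge_rgb(
    l1_map: np.ndarray, l2_map: np.ndarray, l3_map: np.ndarray
) -> np.ndarray:
    """Merge three scaled 8-bit maps into an RGB image.

    Red holds the first eigenvalue, green the second, blue the third.
    """
    maps = [np.asarray(m) for m in (l1_map, l2_map, l3_map)]
    if not (maps[0].shape == maps[1].shape == maps[2].shape):
        raise ValueError(
            f"channel shapes differ: {[m.shape for m in maps]}"
        )
    return np.stack(maps, axis=-1).astype(np.uint8)


def colorize(
    values: np.ndarray,
    vmin: float,
    vmax: float,
    cmap: str = LAMBDA_R_CMAP,
) -> np.ndarray:
    """Map scalar values through a colormap to 8-bit RGB (NaN -> black)."""
    values = np.asarray(values, dtype=float)
    norm = np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = colormaps[cmap](np.where(np.isfinite(norm), norm, 0.0))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~np.isfinite(values)] = 0
    return rgb


def overlay(
    base: np.ndarray, color_map: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Superimpose a color map on a grayscale base image within a mask.

    ``base`` is 2-D (any numeric range; rescaled to 8-bit by its own
    min/max), ``color_map`` is (..., 3) 8-bit RGB of the same spatial
    shape.  Color replaces the base inside the mask; the base shows through
    elsewhere.
    """
    base = np.asarray(base, dtype=float)
    color_map = np.asarray(color_map)
    mask = np.asarray(mask, dtype=bool)
    if color_map.shape[:-1] != base.shape or mask.shape != base.shape:
        raise ValueError(
            f"shape mismatch: base {base.shape}, color {color_map.shape}, "
            f"mask {mask.shape}"
        )
    finite = base[np.isfinite(base)]
    lo = float(finite.min()) if finite.size else 0.0
    hi = float(finite.max()) if finite.size else 1.0
    if hi <= lo:
        gray = np.zeros_like(base, dtype=np.uint8)
    else:
        gray = scale_to_8bit(base, DisplayScaling(lo, hi))
    out = np.repeat(gray[..., None], 3, axis=-1)
    out[mask] = color_map[mask]
    return out
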