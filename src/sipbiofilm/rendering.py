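"""Deterministic visualization of delta and count images.

The display contract mirrors common NanoSIMS practice: winsorize at the
5th/95th percentiles (or clamp to fixed delta bounds, e.g. -200..9000 permil
for delta13C and -200..37000 permil for delta15N), scale to the unit
interval, colorize with the perceptually uniform cividis colormap on a
black background, and fade foreground pixels within a 2-pixel band of the
background toward black.  The fade scales the pixel's perceptual lightness
(L* in CIELAB) by d/(band+1), where d is the Euclidean distance to the
nearest background pixel, leaving the chromatic channels untouched in the
uniform space; pixels beyond the band are bit-identical before and after.

Rendering is pure: same inputs and spec give a byte-identical PNG.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from matplotlib import colormaps
from scipy import ndimage as ndi
from skimage.color import lab2rgb, rgb2lab

from .errors import RenderError, ValidationError


@dataclass
class RenderSpec:
    bounds_mode: str = "percentile"       # "percentile" | "fixed"
    fixed_bounds: tuple | None = None     # (low, high) in data units
    percentiles: tuple = (5.0, 95.0)
    fade_band_px: int = 2
    colormap_name: str = "cividis"
    background_color: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.bounds_mode not in ("percentile", "fixed"):
            raise ValidationError("bounds_mode must be 'percentile' or 'fixed'")
        if self.bounds_mode == "fixed":
            if self.fixed_bounds is None or not self.fixed_bounds[0] < self.fixed_bounds[1]:
                raise ValidationError("fixed mode needs fixed_bounds with low < high")
        else:
            lo, hi = self.percentiles
            if not (0 <= lo < hi <= 100):
                raise ValidationError("percentiles must satisfy 0 <= low < high <= 100")
        if self.fade_band_px < 0:
            raise ValidationError("fade_band_px must be >= 0")


def clip_normalize(image, spec: RenderSpec, valid=None) -> tuple[np.ndarray, tuple]:
    """Winsorize/clamp an image and scale it to [0, 1].

    Returns ``(unit_image, realized_bounds)``.  In percentile mode the
    bounds are the linear-interpolation percentiles of the valid pixels;
    values beyond them are set to the bound (winsorizing) before min-max
    scaling.  Invalid pixels come back as NaN.  A constant image maps to
    all zeros by convention.
    """
    img = np.asarray(image, dtype=np.float64)
    finite = np.isfinite(img)
    if valid is not None:
        finite &= np.asarray(valid, dtype=bool)
    if not finite.any():
        raise RenderError("image has no valid pixels to render")
    vals = img[finite]
    if spec.bounds_mode == "fixed":
        lo, hi = map(float, spec.fixed_bounds)
    else:
        lo, hi = np.percentile(vals, spec.percentiles)
    out = np.full(img.shape, np.nan)
    if hi == lo:
        out[finite] = 0.0
    else:
        out[finite] = (np.clip(img[finite], lo, hi) - lo) / (hi - lo)
    return out, (float(lo), float(hi))


def colorize(unit_image, background_mask, spec: RenderSpec) -> np.ndarray:
    """Map a unit-interval image through the colormap; background painted."""
    cmap = colormaps[spec.colormap_name]
    u = np.nan_to_num(np.asarray(unit_image, dtype=np.float64))
    rgb = np.asarray(cmap(np.clip(u, 0.0, 1.0)))[..., :3]
    bg = np.asarray(background_mask, dtype=bool) | ~np.isfinite(unit_image)
    rgb[bg] = spec.background_color
    return rgb


def fade_edges(rgb_image, background_mask, spec: RenderSpec) -> np.ndarray:
    """Fade foreground pixels near the background toward black.

    A foreground pixel at Euclidean distance d (to the closest background
    pixel) with 0 < d <= fade_band_px has its lightness multiplied by
    d/(fade_band_px+1); hue and chroma are preserved.  Pixels farther than
    the band, and the background itself, are returned unchanged apart from
    the background being painted ``background_color``.
    """
    rgb = np.asarray(rgb_image, dtype=np.float64).copy()
    bg = np.asarray(background_mask, dtype=bool)
    if rgb.shape[:2] != bg.shape:
        raise ValidationError("rgb image and background mask shapes differ")
    rgb[bg] = spec.background_color
    band = spec.fade_band_px
    if band == 0:
        return rgb
    dist = ndi.distance_transform_edt(~bg)
    in_band = (~bg) & (dist <= band)
    if in_band.any():
        factors = dist[in_band] / (band + 1.0)
        lab = rgb2lab(rgb[in_band][None, :, :])[0]
        lab[:, 0] *= factors
        rgb[in_band] = np.clip(lab2rgb(lab[None, :, :])[0], 0.0, 1.0)
    return rgb


def render_delta_png(delta_image, background_mask, spec: RenderSpec, path,
                     valid=None) -> dict:
    """Render a delta image to PNG; returns a provenance dict."""
    unit, bounds = clip_normalize(delta_image, spec, valid=valid)
    rgb = colorize(unit, background_mask, spec)
    rgb = fade_edges(rgb, background_mask, spec)
    save_png(rgb, path)
    return {
        "path": str(path),
        "bounds_mode": spec.bounds_mode,
        "realized_bounds": list(bounds),
        "percentile_definition": "linear_interpolation",
        "fade_band_px": spec.fade_band_px,
        "fade_distance_metric": "euclidean",
        "colormap": spec.colormap_name,
    }


def save_png(rgb_float, path) -> None:
    """Write a float RGB image in [0,1] as a deterministic 8-bit PNG."""
    arr = np.clip(np.asarray(rgb_float) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr, extension=".png")
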