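"""Shading and background correction.

Two alternatives, as the colony pipeline requires one of them to remove
vignetting and well shadows before thresholding:

* rolling-ball background subtraction — the smooth background is the upper
  envelope reachable by a ball of given radius rolled under the intensity
  surface (grayscale opening by a spherical structuring element); features
  narrower than the ball survive, gradients wider than the ball are removed;
* local contrast normalization — each pixel is re-expressed as its deviation
  from the local mean in units of the local standard deviation, recentered
  at 128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

__all__ = ["ShadingParams", "subtract_background", "normalize_local_contrast"]


@dataclass(frozen=True)
class ShadingParams:
    """Colony-pipeline shading choice: which correction and its knobs."""

    method: str = "subtract_background"  # or "normalize_local_contrast" / "none"
    radius: float = 50.0                 # rolling-ball radius, px
    light_background: bool = True
    block_radius: int = 40               # NLC window radius, px
    stddevs: float = 3.0

    def __post_init__(self) -> None:
        if self.method not in ("subtract_background", "normalize_local_contrast", "none"):
            raise ValueError(f"unknown shading method {self.method!r}")
        if self.radius <= 0 or self.block_radius <= 0 or self.stddevs <= 0:
            raise ValueError("shading radii and stddev factor must be > 0")

    def apply(self, image: np.ndarray) -> np.ndarray:
        if self.method == "subtract_background":
            return subtract_background(image, self.radius, self.light_background)
        if self.method == "normalize_local_contrast":
            return normalize_local_contrast(image, self.block_radius, self.stddevs)
        return np.asarray(image).copy()


def _ball_surface(radius: float) -> np.ndarray:
    """Height profile of the ball: 0 at the centre, -radius outside support."""
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = x * x + y * y
    with np.errstate(invalid="ignore"):
        h = np.sqrt(np.maximum(radius * radius - d2, 0.0)) - radius
    h[d2 > radius * radius] = -np.inf
    return h


def subtract_background(
    image: np.ndarray, radius: float, light_background: bool = False
) -> np.ndarray:
    """Rolling-ball background subtraction, exact (no shrink approximation).

    Dark-background mode rolls the ball under the surface (grayscale opening
    with a spherical element) and subtracts it; light-background mode rolls
    it on top (closing) and subtracts while re-anchoring the background at
    255, preserving the dark-features-on-light convention. Output is clipped
    to [0, 255].
    """
    if radius < 1:
        raise ValueError(f"rolling-ball radius must be >= 1, got {radius}")
    arr = np.asarray(image, dtype=float)
    ball = _ball_surface(radius)
    footprint = np.isfinite(ball)
    structure = np.where(footprint, ball, 0.0)
    if light_background:
        bg = ndi.grey_closing(arr, structure=structure, footprint=footprint, mode="nearest")
        out = arr - bg + 255.0
    else:
        bg = ndi.grey_opening(arr, structure=structure, footprint=footprint, mode="nearest")
        out = arr - bg
    out = np.clip(out, 0.0, 255.0)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.floor(out + 0.5).astype(np.uint8)
    return out


def _window_sums(arr: np.ndarray, r: int) -> np.ndarray:
    """Sum of arr over a (2r+1)^2 window via a summed-area table, with the
    window cropped at the image edge."""
    h, w = arr.shape
    sat = np.zeros((h + 1, w + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=sat[1:, 1:])
    y0 = np.clip(np.arange(h) - r, 0, h)
    y1 = np.clip(np.arange(h) + r + 1, 0, h)
    x0 = np.clip(np.arange(w) - r, 0, w)
    x1 = np.clip(np.arange(w) + r + 1, 0, w)
    return (
        sat[np.ix_(y1, x1)] - sat[np.ix_(y0, x1)]
        - sat[np.ix_(y1, x0)] + sat[np.ix_(y0, x0)]
    )


def normalize_local_contrast(
    image: np.ndarray, block_radius: int, stddevs: float
) -> np.ndarray:
    """Per-pixel standardization against local mean and stddev.

    ``out = 128 + (v - mean_local) * 128 / (stddevs * std_local)``, clipped to
    [0, 255]: a pixel ``stddevs`` standard deviations above its local mean
    saturates at 255. Local statistics use a (2r+1)^2 window computed with
    summed-area tables (cropped at the borders). Flat regions map to 128.
    """
    if block_radius < 1:
        raise ValueError(f"block radius must be >= 1, got {block_radius}")
    if stddevs <= 0:
        raise ValueError(f"stddev factor must be > 0, got {stddevs}")
    arr = np.asarray(image, dtype=float)
    r = int(block_radius)
    ones = _window_sums(np.ones_like(arr), r)
    mean = _window_sums(arr, r) / ones
    var = _window_sums(arr * arr, r) / ones - mean * mean
    std = np.sqrt(np.maximum(var, 0.0))
    out = np.where(
        std > 1e-9,
        128.0 + (arr - mean) * (128.0 / (stddevs * np.maximum(std, 1e-9))),
        128.0,
    )
    out = np.clip(out, 0.0, 255.0)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        return np.floor(out + 0.5).astype(np.uint8)
    return out
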