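"""Histogram-contrast visual saliency.

A gray level is salient in proportion to its total intensity distance
from every pixel in the image: with hist(i) the count of pixels at
quantised level i,

    Sal(j) = sum_i hist(i) * |j - i|,   j in 0..255.

The per-pixel map is a lookup of Sal at each pixel's level, min-max
normalised to [0,1] so it can serve directly as a fusion weight.  It
depends only on the histogram, hence is invariant to any spatial
rearrangement of the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SaliencyMap", "vsm"]


@dataclass(frozen=True)
class SaliencyMap:
    """Normalised per-pixel saliency plus the raw 256-entry level LUT."""

    values: np.ndarray
    lut: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def quantize_255(img: np.ndarray) -> np.ndarray:
    """Quantise a [0,1] float image to integer levels 0..255."""
    levels = np.floor(np.asarray(img, dtype=np.float64) * 255.0 + 0.5)
    return np.clip(levels, 0, 255).astype(np.intp)


def vsm(img: np.ndarray) -> SaliencyMap:
    """Histogram-contrast visual saliency map of a gray image.

    For a constant image (degenerate histogram) the map is 0.5
    everywhere, so downstream weighted averaging reduces to a plain
    mean.
    """
    levels = quantize_255(img)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    grid = np.arange(256, dtype=np.float64)
    # |j - i| distance matrix contracted against the histogram.
    lut = np.abs(grid[:, None] - grid[None, :]) @ hist
    raw = lut[levels]
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        values = np.full(img.shape, 0.5)
    else:
        values = (raw - lo) / (hi - lo)
    return SaliencyMap(values=values, lut=lut)
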