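"""Image I/O and luminance/chroma conversion.

All fusion-core computation runs on single-channel floating-point images
with a nominal [0,1] intensity scale (the ``im2double`` convention).
Pseudo-colour functional images (SPECT/PET renderings) are split into a
luminance plane, which enters the fusion pipeline, and a chroma pair,
which is carried through untouched and re-attached to the fused
luminance at the end.

The colour transform is full-range ITU-R BT.601 YCbCr, which is exactly
invertible in floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ChromaPair",
    "read_image",
    "write_image",
    "rgb_to_ycbcr",
    "ycbcr_to_rgb",
    "as_image_f",
]

log = logging.getLogger(__name__)

# Full-range BT.601 forward matrix, rows -> (Y, Cb, Cr).
_FWD = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_INV = np.linalg.inv(_FWD)


@dataclass(frozen=True)
class ChromaPair:
    """Chroma planes accompanying a luminance image (centred at 0.5)."""

    cb: np.ndarray
    cr: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.cb.shape

    @staticmethod
    def neutral(shape: tuple[int, int]) -> "ChromaPair":
        half = np.full(shape, 0.5)
        return ChromaPair(half, half.copy())


def as_image_f(arr: np.ndarray) -> np.ndarray:
    """Validate a 2-D float image: finite, at least 2x2, float64."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {a.shape}")
    if a.shape[0] < 2 or a.shape[1] < 2:
        raise ValueError(f"image too small for fusion: shape {a.shape}, need >= 2x2")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains NaN or Inf values")
    return a


def read_image(path: str | Path, collapse_gray_rgb: bool = False) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image and map it onto the [0,1] float scale.

    8-bit inputs are divided by 255, 16-bit by 65535.  A single-channel
    file yields a 2-D array; a 3-channel file a (H, W, 3) RGB array.  An
    alpha channel is dropped with a warning.  With ``collapse_gray_rgb``
    an RGB file whose channels are elementwise identical is collapsed to
    a single 2-D plane.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures vary by plugin
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if raw.dtype == np.uint8:
        arr = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        arr = raw.astype(np.float64) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        arr = raw.astype(np.float64)
    else:
        raise ValueError(f"unsupported image dtype {raw.dtype} in {path}")

    if arr.ndim == 2:
        return as_image_f(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            log.warning("dropping alpha channel of %s", path)
            arr = arr[:, :, :3]
        if arr.shape[2] == 2:  # gray+alpha
            log.warning("dropping alpha channel of %s", path)
            return as_image_f(arr[:, :, 0])
        if arr.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {arr.shape[2]} in {path} (want 1 or 3)"
            )
        if collapse_gray_rgb and np.array_equal(arr[:, :, 0], arr[:, :, 1]) and np.array_equal(
            arr[:, :, 0], arr[:, :, 2]
        ):
            return as_image_f(arr[:, :, 0])
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"image {path} contains NaN or Inf")
        return arr
    raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a float image as 8-bit, clipping to [0,1] and rounding.

    Quantisation is round-half-away-from-zero (``v*255 + 0.5`` floored),
    matching the common imaging convention.
    """
    path = Path(path)
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim not in (2, 3):
        raise ValueError(f"cannot write array of shape {arr.shape} as an image")
    clipped = np.clip(arr, 0.0, 1.0)
    q = np.floor(clipped * 255.0 + 0.5).astype(np.uint8)
    try:
        iio.imwrite(path, q)
    except Exception as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def rgb_to_ycbcr(img: np.ndarray) -> tuple[np.ndarray, ChromaPair]:
    """Split an RGB image into luminance and chroma (full-range BT.601).

    Returns the luma plane Y = 0.299 R + 0.587 G + 0.114 B (the gray
    image that enters fusion) and the (Cb, Cr) offsets centred at 0.5.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    y = arr @ _FWD[0]
    cb = arr @ _FWD[1] + 0.5
    cr = arr @ _FWD[2] + 0.5
    return y, ChromaPair(cb, cr)


def ycbcr_to_rgb(luma: np.ndarray, chroma: ChromaPair, clip: bool = True) -> np.ndarray:
    """Exact algebraic inverse of :func:`rgb_to_ycbcr`, then clip to [0,1]."""
    y = np.asarray(luma, dtype=np.float64)
    if y.shape != chroma.cb.shape or y.shape != chroma.cr.shape:
        raise ValueError(
            f"luma shape {y.shape} does not match chroma shape {chroma.cb.shape}"
        )
    ycc = np.stack([y, chroma.cb - 0.5, chroma.cr - 0.5], axis=-1)
    rgb = ycc @ _INV.T
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb
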