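"""Deterministic synthetic phantom pairs for fusion testing.

Generates co-registered pairs that mimic the complementary content of
multimodal brain imagery: a structural phantom (MRI/CT-like) that is
edge- and texture-rich — nested elliptical "skull"/"tissue" outlines
with a band of fine sinusoidal texture — and a functional phantom
(SPECT/PET-like) made of smooth Gaussian activity blobs rendered
through a hot-iron colour ramp.  Every pixel is a pure function of
(size, seed, noise_sigma), so regeneration is bit-identical.

These phantoms exercise the decomposition, saliency, fusion and colour
paths; they make no claim to anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhantomPair", "make_pair", "make_gray_pair", "hot_iron"]


@dataclass(frozen=True)
class PhantomPair:
    """Co-registered structural (gray) and functional (RGB) phantoms."""

    structural: np.ndarray
    functional: np.ndarray
    seed: int
    size: int


def hot_iron(v: np.ndarray) -> np.ndarray:
    """Map [0,1] activity to the hot-iron ramp black->red->yellow->white."""
    v = np.clip(np.asarray(v, dtype=np.float64), 0.0, 1.0)
    r = np.clip(3.0 * v, 0.0, 1.0)
    g = np.clip(3.0 * v - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * v - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return (y - c).astype(np.float64), (x - c).astype(np.float64)


def _ellipse_radius(y: np.ndarray, x: np.ndarray, a: float, b: float) -> np.ndarray:
    return np.sqrt((x / a) ** 2 + (y / b) ** 2)


def _check_size(size: int) -> None:
    if size < 64:
        raise ValueError(f"phantom size must be >= 64, got {size}")


def _structural(size: int, rng: np.random.Generator, noise_sigma: float) -> np.ndarray:
    y, x = _grid(size)
    a0 = size * rng.uniform(0.42, 0.46)
    b0 = size * rng.uniform(0.38, 0.42)
    r = _ellipse_radius(y, x, a0, b0)

    img = np.zeros((size, size))
    img[r < 1.0] = 0.35  # soft-tissue fill

    # 2-4 nested outlines ("skull" and tissue interfaces) at distinct grays
    n_rings = int(rng.integers(2, 5))
    ring_scales = np.sort(rng.uniform(0.45, 1.0, size=n_rings))[::-1]
    ring_grays = rng.uniform(0.55, 1.0, size=n_rings)
    thickness = 2.5 / min(a0, b0)
    for scale, gray in zip(ring_scales, ring_grays):
        img[np.abs(r - scale) < thickness] = gray

    # fine sinusoidal texture band inside the innermost ring
    inner = ring_scales[-1] * 0.85
    period = rng.uniform(2.0, 4.0)
    theta = rng.uniform(0.0, np.pi)
    u = np.cos(theta) * x + np.sin(theta) * y
    v = -np.sin(theta) * x + np.cos(theta) * y
    texture = 0.18 * np.sin(2.0 * np.pi * u / period) * np.sin(2.0 * np.pi * v / period)
    band = r < inner
    img[band] += texture[band]

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _functional_activity(size: int, rng: np.random.Generator) -> np.ndarray:
    y, x = _grid(size)
    a0 = size * 0.44
    b0 = size * 0.40
    r = _ellipse_radius(y, x, a0, b0)
    n_blobs = int(rng.integers(2, 4))
    act = np.zeros((size, size))
    for _ in range(n_blobs):
        cy = rng.uniform(-0.4, 0.4) * b0
        cx = rng.uniform(-0.4, 0.4) * a0
        sig = rng.uniform(size / 10.0, size / 6.0)
        amp = rng.uniform(0.5, 1.0)
        act += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sig**2))
    act = np.clip(act, 0.0, 1.0)
    act[r >= 1.0] = 0.0
    return act


def make_pair(size: int, seed: int, noise_sigma: float = 0.0) -> PhantomPair:
    """Generate a structural/functional phantom pair.

    The structural image carries the high-frequency content (outlines,
    texture); the functional RGB image is smooth with saturated
    pseudo-colour, so its luminance gradient is far below the
    structural one — the same asymmetry real MRI-PET/SPECT pairs show.
    """
    _check_size(size)
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    structural = _structural(size, rng, noise_sigma)
    functional = hot_iron(_functional_activity(size, rng))
    return PhantomPair(structural=structural, functional=functional, seed=seed, size=size)


def make_gray_pair(
    size: int, seed: int, noise_sigma: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a CT-MRI style gray pair with complementary content.

    The first image is the textured structural phantom; the second
    emphasises the outer ellipse as a bright "bone" ring over a flat
    interior, the way CT complements MRI soft-tissue detail.
    """
    _check_size(size)
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    structural = _structural(size, rng, noise_sigma)

    y, x = _grid(size)
    a0 = size * rng.uniform(0.42, 0.46)
    b0 = size * rng.uniform(0.38, 0.42)
    r = _ellipse_radius(y, x, a0, b0)
    ct = np.zeros((size, size))
    ct[r < 1.0] = 0.25  # flat interior
    ct[np.abs(r - 0.97) < 3.0 / min(a0, b0)] = 0.95  # bone ring
    if noise_sigma > 0:
        ct += rng.normal(0.0, noise_sigma, size=ct.shape)
    return structural, np.clip(ct, 0.0, 1.0)
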