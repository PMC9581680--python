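"""Fusion rules for base and detail layers.

Base layers are merged by a saliency-weighted average whose weights sum
to one pointwise.  Detail layers are merged by max-absolute selection,
softened by a small Gaussian blur of the binary selection map, and then
shrunk by a per-pixel weighted-least-squares (WLS) step that suppresses
detail in low-activity regions — a closed-form noise-aware cleanup of
the fused high-frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import IRGFParams, gaussian_smooth
from .msd import DecompositionResult
from .saliency import SaliencyMap

__all__ = [
    "FusionConfig",
    "FusedLayers",
    "fuse_base",
    "absmax_map",
    "fuse_details_level",
    "fuse_all",
    "reconstruct_fused",
]


@dataclass(frozen=True)
class FusionConfig:
    """All tunable parameters of the fusion pipeline with their defaults.

    levels
        Number of decomposition levels n (default 4).
    irgf
        Rolling-guidance parameters: sigma_s=2, sigma_r=0.05, 4
        recovery iterations, Wiener radius 3 with noise floor 0.01.
    scale_factor
        Multiplier of sigma_s between successive levels (default 2).
    gauss_w, gauss_sigma
        Size and standard deviation of the Gaussian that softens the
        binary max-absolute selection map (3 and 1.0).
    wls_lambda
        Strength of the WLS detail shrinkage (0.01); 0 disables it.
    wls_activity_sigma, wls_activity_eps
        Scale of the local-energy activity estimate driving the
        shrinkage, and its divide-by-zero guard.
    """

    levels: int = 4
    irgf: IRGFParams = field(default_factory=IRGFParams)
    scale_factor: float = 2.0
    gauss_w: int = 3
    gauss_sigma: float = 1.0
    wls_lambda: float = 0.01
    wls_activity_sigma: float = 2.0
    wls_activity_eps: float = 1e-4

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.gauss_w < 1 or self.gauss_w % 2 == 0:
            raise ValueError(f"gauss_w must be odd >= 1, got {self.gauss_w}")
        if self.gauss_sigma <= 0 or self.wls_activity_sigma <= 0:
            raise ValueError("Gaussian sigmas must be positive")
        if self.wls_lambda < 0:
            raise ValueError(f"wls_lambda must be >= 0, got {self.wls_lambda}")
        if self.wls_activity_eps <= 0:
            raise ValueError("wls_activity_eps must be positive")


@dataclass(frozen=True)
class FusedLayers:
    """Fused base layer and per-level fused detail layers."""

    base_f: np.ndarray
    details_f: tuple[np.ndarray, ...]

    @property
    def levels(self) -> int:
        return len(self.details_f)


def _check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch among fusion inputs: {sorted(shapes)}")


def fuse_base(
    bA: np.ndarray, bB: np.ndarray, vA: SaliencyMap, vB: SaliencyMap
) -> np.ndarray:
    """Saliency-weighted average of the two base layers.

    Weights wA = 1/2 + (vA - vB)/2 and wB = 1/2 + (vB - vA)/2 sum to
    one pointwise, so the output is a pointwise convex combination of
    the inputs; equal saliency yields the plain mean.
    """
    bA = np.asarray(bA, dtype=np.float64)
    bB = np.asarray(bB, dtype=np.float64)
    _check_same_shape(bA, bB, vA.values, vB.values)
    wA = 0.5 + (vA.values - vB.values) / 2.0
    return wA * bA + (1.0 - wA) * bB


def absmax_map(dA: np.ndarray, dB: np.ndarray) -> np.ndarray:
    """Binary selection map of the max-absolute rule.

    1 where |dA| < |dB| (the functional image's coefficient wins),
    0 elsewhere; ties go to 0, keeping the structural image's detail.
    """
    dA = np.asarray(dA, dtype=np.float64)
    dB = np.asarray(dB, dtype=np.float64)
    _check_same_shape(dA, dB)
    return (np.abs(dA) < np.abs(dB)).astype(np.float64)


def wls_activity(dA: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Inverse local-energy activity weight of the WLS shrinkage.

    Smooths |dA| (the structural detail's magnitude) and inverts it, so
    flat regions — where residual detail is likely noise — get large
    weights and hence strong shrinkage.
    """
    energy = gaussian_smooth(np.abs(dA), cfg.gauss_w, cfg.wls_activity_sigma)
    return 1.0 / (energy + cfg.wls_activity_eps)


def fuse_details_level(
    dA: np.ndarray, dB: np.ndarray, cfg: FusionConfig
) -> np.ndarray:
    """Fuse one pair of detail layers.

    (i) binary max-absolute map, (ii) Gaussian-softened into a weight
    G in [0,1], (iii) preliminary detail I_D = (1-G) dA + G dB, (iv)
    per-pixel WLS optimum of (x - I_D)^2 + lambda * a * x^2, which in
    closed form shrinks I_D by 1 / (1 + lambda * a).  The shrinkage
    never amplifies: |output| <= |I_D| pointwise.
    """
    dA = np.asarray(dA, dtype=np.float64)
    dB = np.asarray(dB, dtype=np.float64)
    _check_same_shape(dA, dB)
    m = absmax_map(dA, dB)
    g = gaussian_smooth(m, cfg.gauss_w, cfg.gauss_sigma)
    prelim = (1.0 - g) * dA + g * dB
    if cfg.wls_lambda == 0.0:
        return prelim
    a = wls_activity(dA, cfg)
    return prelim / (1.0 + cfg.wls_lambda * a)


def fuse_all(
    decA: DecompositionResult,
    decB: DecompositionResult,
    vA: SaliencyMap,
    vB: SaliencyMap,
    cfg: FusionConfig | None = None,
) -> FusedLayers:
    """Fuse every layer of two decompositions of the same depth."""
    if cfg is None:
        cfg = FusionConfig()
    if decA.levels != decB.levels:
        raise ValueError(
            f"decompositions have different depths: {decA.levels} vs {decB.levels}"
        )
    base_f = fuse_base(decA.base, decB.base, vA, vB)
    details_f = tuple(
        fuse_details_level(da, db, cfg)
        for da, db in zip(decA.details, decB.details)
    )
    return FusedLayers(base_f=base_f, details_f=details_f)


def reconstruct_fused(f: FusedLayers) -> np.ndarray:
    """Sum the fused base and detail layers; no clipping here."""
    out = f.base_f.copy()
    for d in f.details_f:
        if d.shape != out.shape:
            raise ValueError(
                f"fused detail shape {d.shape} does not match base {out.shape}"
            )
        out += d
    return out
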