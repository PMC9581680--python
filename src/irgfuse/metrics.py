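"""Fusion quality metrics: SF, SSIM, CF, ESF, AG, VIF.

Gradient-type scores (SF, ESF, AG, CF) are computed on the 0-255 scale
so their magnitudes match the values conventionally reported for 8-bit
imagery; SSIM and VIF are scale-aware by construction.  All six are
"bigger is better" sharpness / fidelity measures.  For a fused image
against its two sources, the reference-based scores (SSIM, VIF) are
averaged over the sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import fftconvolve
from skimage.metrics import structural_similarity

from .filters import gaussian_kernel_2d

__all__ = [
    "MetricsReport",
    "spatial_frequency",
    "extended_spatial_frequency",
    "average_gradient",
    "clarity",
    "ssim_pair",
    "vif_pair",
    "fusion_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    """The six quality scores of one fused image against its sources."""

    sf: float
    ssim: float
    cf: float
    esf: float
    ag: float
    vif: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def _scaled(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64) * 255.0


def spatial_frequency(img: np.ndarray) -> float:
    """Spatial frequency: RMS of row and column first differences.

    SF = sqrt(RF^2 + CF^2) with RF the root-mean-square horizontal
    difference and CF the vertical one, on the 0-255 scale.
    """
    a = _scaled(img)
    rf2 = np.mean(np.diff(a, axis=1) ** 2)
    cf2 = np.mean(np.diff(a, axis=0) ** 2)
    return float(np.sqrt(rf2 + cf2))


def extended_spatial_frequency(img: np.ndarray) -> float:
    """Spatial frequency extended with the two diagonal directions.

    Diagonal first differences are scaled by 1/sqrt(2) (unit step along
    a diagonal) before entering the RMS.
    """
    a = _scaled(img)
    rf2 = np.mean(np.diff(a, axis=1) ** 2)
    cf2 = np.mean(np.diff(a, axis=0) ** 2)
    main_d = (a[1:, 1:] - a[:-1, :-1]) / np.sqrt(2.0)
    sec_d = (a[1:, :-1] - a[:-1, 1:]) / np.sqrt(2.0)
    mdf2 = np.mean(main_d**2)
    sdf2 = np.mean(sec_d**2)
    return float(np.sqrt(rf2 + cf2 + mdf2 + sdf2))


def average_gradient(img: np.ndarray) -> float:
    """Mean of sqrt((dx^2 + dy^2)/2) over the interior forward-difference grid."""
    a = _scaled(img)
    dx = a[:-1, 1:] - a[:-1, :-1]
    dy = a[1:, :-1] - a[:-1, :-1]
    return float(np.mean(np.sqrt((dx**2 + dy**2) / 2.0)))


def clarity(img: np.ndarray) -> float:
    """Mean gradient magnitude sqrt(dx^2 + dy^2); equals sqrt(2) * AG."""
    a = _scaled(img)
    dx = a[:-1, 1:] - a[:-1, :-1]
    dy = a[1:, :-1] - a[:-1, :-1]
    return float(np.mean(np.sqrt(dx**2 + dy**2)))


def ssim_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Mean single-scale SSIM with the standard 11x11 sigma-1.5 Gaussian window."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < 11:
        raise ValueError(
            f"image of shape {x.shape} smaller than the 11x11 SSIM window"
        )
    return float(
        structural_similarity(
            x,
            y,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=1.0,
        )
    )


def _vif_filter_valid(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(img, kernel, mode="valid")


def vif_pair(ref: np.ndarray, dist: np.ndarray) -> float:
    """Pixel-domain visual information fidelity (VIFP).

    Four dyadic scales of Gaussian blur + downsample-by-2; per scale,
    windowed variances and covariances feed a Gaussian scale-mixture
    channel model with noise variance 2 on the 0-255 scale.  The score
    is the ratio of summed log-information terms of the distorted and
    the reference channel; identical images score 1, an uninformative
    (constant) distorted image scores ~0.  Scales whose filtered image
    would be empty are skipped with a log message.
    """
    ref = _scaled(ref)
    dist = _scaled(dist)
    if ref.shape != dist.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {dist.shape}")
    sigma_nsq = 2.0
    eps = 1e-10
    num = 0.0
    den = 0.0
    scales_used = 0
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        win = gaussian_kernel_2d(n, n / 5.0)
        if scale > 1:
            if min(ref.shape) < n:
                break
            ref = _vif_filter_valid(ref, win)[::2, ::2]
            dist = _vif_filter_valid(dist, win)[::2, ::2]
        if min(ref.shape) < n:
            break
        mu1 = _vif_filter_valid(ref, win)
        mu2 = _vif_filter_valid(dist, win)
        mu1_sq = mu1 * mu1
        mu2_sq = mu2 * mu2
        sigma1_sq = _vif_filter_valid(ref * ref, win) - mu1_sq
        sigma2_sq = _vif_filter_valid(dist * dist, win) - mu2_sq
        sigma12 = _vif_filter_valid(ref * dist, win) - mu1 * mu2
        np.maximum(sigma1_sq, 0.0, out=sigma1_sq)
        np.maximum(sigma2_sq, 0.0, out=sigma2_sq)

        g = sigma12 / (sigma1_sq + eps)
        sv_sq = sigma2_sq - g * sigma12

        g = np.where(sigma1_sq < eps, 0.0, g)
        sv_sq = np.where(sigma1_sq < eps, sigma2_sq, sv_sq)
        sigma1_sq = np.where(sigma1_sq < eps, 0.0, sigma1_sq)

        g = np.where(sigma2_sq < eps, 0.0, g)
        sv_sq = np.where(sigma2_sq < eps, 0.0, sv_sq)

        sv_sq = np.where(g < 0.0, sigma2_sq, sv_sq)
        g = np.maximum(g, 0.0)
        sv_sq = np.maximum(sv_sq, eps)

        num += np.sum(np.log10(1.0 + g * g * sigma1_sq / (sv_sq + sigma_nsq)))
        den += np.sum(np.log10(1.0 + sigma1_sq / sigma_nsq))
        scales_used += 1
    if scales_used == 0:
        raise ValueError(f"image of shape {ref.shape} too small for VIF")
    if scales_used < 4:
        log.info("VIF computed over %d of 4 scales (small image)", scales_used)
    if den == 0.0:
        return 1.0  # reference carries no information; nothing was lost
    return float(num / den)


def fusion_report(
    srcA: np.ndarray, srcB: np.ndarray, fused: np.ndarray
) -> MetricsReport:
    """Score a fused image: sharpness of the fusion itself, fidelity vs both sources."""
    srcA = np.asarray(srcA, dtype=np.float64)
    srcB = np.asarray(srcB, dtype=np.float64)
    fused = np.asarray(fused, dtype=np.float64)
    if not (srcA.shape == srcB.shape == fused.shape):
        raise ValueError(
            f"shape mismatch: {srcA.shape}, {srcB.shape}, {fused.shape}"
        )
    return MetricsReport(
        sf=spatial_frequency(fused),
        ssim=(ssim_pair(srcA, fused) + ssim_pair(srcB, fused)) / 2.0,
        cf=clarity(fused),
        esf=extended_spatial_frequency(fused),
        ag=average_gradient(fused),
        vif=(vif_pair(srcA, fused) + vif_pair(srcB, fused)) / 2.0,
    )
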