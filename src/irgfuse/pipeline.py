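"""End-to-end fusion orchestration.

The pipeline fuses a structural gray image (MRI or CT) with a
functional image that is either gray (CT) or pseudo-colour RGB
(SPECT/PET).  A colour functional image is first split into luminance
and chroma; fusion runs entirely on the two gray channels; the fused
luminance then takes over the functional image's untouched chroma.

Stages: multiscale rolling-guidance decomposition of both gray inputs,
histogram-contrast saliency of the *original* full-resolution inputs,
saliency-weighted base fusion, max-absolute + WLS detail fusion, and
additive reconstruction.  No stage uses randomness, so two runs on
identical inputs are bit-identical.  The output is returned unclipped;
clipping happens only at write time.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .fusion_rules import FusionConfig, fuse_all, reconstruct_fused
from .io_color import ChromaPair, as_image_f, rgb_to_ycbcr, ycbcr_to_rgb
from .msd import decompose
from .saliency import vsm

__all__ = ["RunConfig", "fuse_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Fusion parameters plus run-level options for the CLI."""

    fusion: FusionConfig = field(default_factory=FusionConfig)
    dump_intermediates: bool = False


def fuse_pipeline(
    structural: np.ndarray,
    functional: np.ndarray,
    cfg: FusionConfig | None = None,
    intermediates: dict[str, Any] | None = None,
) -> np.ndarray:
    """Fuse a co-registered structural/functional image pair.

    Parameters
    ----------
    structural
        2-D gray image (the detail-rich modality, role "A").
    functional
        2-D gray image or (H, W, 3) RGB pseudo-colour image (role "B").
    cfg
        Fusion parameters; defaults reproduce the method's reference
        settings (4 levels, sigma_s=2, sigma_r=0.05, T=4, Wiener r=3
        with noise floor 0.01, 3x3 selection-map Gaussian, WLS
        lambda=0.01).
    intermediates
        Optional dict that, if given, is filled with the per-stage
        products (decompositions, saliency maps, chroma, fused layers)
        for inspection and dumping.

    Returns
    -------
    The fused image, gray if both inputs were gray, RGB otherwise;
    values unclipped.
    """
    if cfg is None:
        cfg = FusionConfig()
    structural = as_image_f(structural)
    functional = np.asarray(functional, dtype=np.float64)

    is_color = functional.ndim == 3
    chroma: ChromaPair | None = None
    if is_color:
        y_func, chroma = rgb_to_ycbcr(functional)
    else:
        y_func = as_image_f(functional)

    if structural.shape != y_func.shape:
        raise ValueError(
            "inputs are not co-registered: structural shape "
            f"{structural.shape} vs functional shape {y_func.shape}"
        )

    t0 = time.perf_counter()
    dec_a = decompose(structural, cfg.levels, cfg.irgf, cfg.scale_factor)
    dec_b = decompose(y_func, cfg.levels, cfg.irgf, cfg.scale_factor)
    t1 = time.perf_counter()
    log.info("decomposition: %.3fs (n=%d)", t1 - t0, cfg.levels)

    # saliency from the full-resolution source images, not base layers
    v_a = vsm(structural)
    v_b = vsm(y_func)
    t2 = time.perf_counter()
    log.info("saliency: %.3fs", t2 - t1)

    fused_layers = fuse_all(dec_a, dec_b, v_a, v_b, cfg)
    fused_luma = reconstruct_fused(fused_layers)
    t3 = time.perf_counter()
    log.info("fusion + reconstruction: %.3fs", t3 - t2)

    if intermediates is not None:
        intermediates.update(
            dec_structural=dec_a,
            dec_functional=dec_b,
            vsm_structural=v_a,
            vsm_functional=v_b,
            chroma=chroma,
            fused_layers=fused_layers,
            fused_luma=fused_luma,
        )

    if is_color:
        assert chroma is not None
        return ycbcr_to_rgb(fused_luma, chroma)
    return fused_luma
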