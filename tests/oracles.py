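"""Independent brute-force reference implementations used as test oracles.

Everything here is written as explicit per-pixel / per-window loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def window_bounds(i: int, j: int, r: int, h: int, w: int):
    return max(0, i - r), min(h, i + r + 1), max(0, j - r), min(w, j + r + 1)


def box_mean_oracle(img: np.ndarray, r: int) -> np.ndarray:
    h, w = img.shape
    out = np.empty_like(img, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            i0, i1, j0, j1 = window_bounds(i, j, r, h, w)
            out[i, j] = img[i0:i1, j0:j1].mean()
    return out


def wiener_oracle(img: np.ndarray, r: int, eps: float) -> np.ndarray:
    h, w = img.shape
    out = np.empty_like(img, dtype=np.float64)
    for i in range(h):
        for j in range(w):
            i0, i1, j0, j1 = window_bounds(i, j, r, h, w)
            patch = img[i0:i1, j0:j1]
            mu = patch.mean()
            m = max((patch**2).mean() - mu**2, 0.0)
            q = m / (m + eps)
            out[i, j] = mu + q * (img[i, j] - mu)
    return out


def guided_oracle(guide: np.ndarray, src: np.ndarray, r: int, eps: float) -> np.ndarray:
    h, w = guide.shape
    a = np.empty((h, w))
    b = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            i0, i1, j0, j1 = window_bounds(i, j, r, h, w)
            gp = guide[i0:i1, j0:j1]
            sp = src[i0:i1, j0:j1]
            mg, ms = gp.mean(), sp.mean()
            cov = (gp * sp).mean() - mg * ms
            var = (gp * gp).mean() - mg * mg
            ak = cov / (var + eps)
            a[i, j] = ak
            b[i, j] = ms - ak * mg
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            i0, i1, j0, j1 = window_bounds(i, j, r, h, w)
            out[i, j] = a[i0:i1, j0:j1].mean() * guide[i, j] + b[i0:i1, j0:j1].mean()
    return out


def gaussian_kernel_oracle(ksize: int, sigma: float) -> np.ndarray:
    c = (ksize - 1) / 2.0
    k = np.empty((ksize, ksize))
    for i in range(ksize):
        for j in range(ksize):
            k[i, j] = np.exp(-((i - c) ** 2 + (j - c) ** 2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_conv_oracle(img: np.ndarray, ksize: int, sigma: float) -> np.ndarray:
    """Nested-loop Gaussian correlation with edge replication."""
    h, w = img.shape
    kern = gaussian_kernel_oracle(ksize, sigma)
    r = ksize // 2
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    acc += kern[di + r, dj + r] * img[ii, jj]
            out[i, j] = acc
    return out


def vsm_lut_oracle(levels: np.ndarray) -> np.ndarray:
    """O(pixels * 256) double loop over pixels and gray levels."""
    lut = np.zeros(256)
    flat = levels.ravel()
    for j in range(256):
        s = 0.0
        for px in flat:
            s += abs(j - px)
        lut[j] = s
    return lut


def ssim_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Direct windowed evaluation of the SSIM formula.

    11x11 Gaussian window (sigma 1.5) applied at every fully-interior
    position; population (weighted) statistics; C1=(0.01)^2,
    C2=(0.03)^2 on the [0,1] scale.
    """
    win = gaussian_kernel_oracle(11, 1.5)
    r = 5
    h, w = x.shape
    c1, c2 = 0.01**2, 0.03**2
    vals = []
    for i in range(r, h - r):
        for j in range(r, w - r):
            xp = x[i - r : i + r + 1, j - r : j + r + 1]
            yp = y[i - r : i + r + 1, j - r : j + r + 1]
            mx = (win * xp).sum()
            my = (win * yp).sum()
            vx = (win * xp * xp).sum() - mx * mx
            vy = (win * yp * yp).sum() - my * my
            cxy = (win * xp * yp).sum() - mx * my
            s = ((2 * mx * my + c1) * (2 * cxy + c2)) / (
                (mx * mx + my * my + c1) * (vx + vy + c2)
            )
            vals.append(s)
    return float(np.mean(vals))


def vifp_oracle(ref: np.ndarray, dist: np.ndarray) -> float:
    """Per-window loop evaluation of the pixel-domain VIF equations.

    Mirrors the dyadic-scale GSM formulation (noise variance 2 on the
    0-255 scale) using explicit window loops and direct decimation.
    """
    ref = ref * 255.0
    dist = dist * 255.0
    sigma_nsq = 2.0
    eps = 1e-10
    num = den = 0.0
    for scale in range(1, 5):
        n = 2 ** (4 - scale + 1) + 1
        win = gaussian_kernel_oracle(n, n / 5.0)
        if scale > 1:
            if min(ref.shape) < n:
                break
            ref = _valid_conv_loop(ref, win)[::2, ::2]
            dist = _valid_conv_loop(dist, win)[::2, ::2]
        if min(ref.shape) < n:
            break
        h, w = ref.shape
        for i in range(h - n + 1):
            for j in range(w - n + 1):
                rp = ref[i : i + n, j : j + n]
                dp = dist[i : i + n, j : j + n]
                mu1 = (win * rp).sum()
                mu2 = (win * dp).sum()
                s1 = max((win * rp * rp).sum() - mu1 * mu1, 0.0)
                s2 = max((win * dp * dp).sum() - mu2 * mu2, 0.0)
                s12 = (win * rp * dp).sum() - mu1 * mu2
                g = s12 / (s1 + eps)
                sv = s2 - g * s12
                if s1 < eps:
                    g, sv, s1 = 0.0, s2, 0.0
                if s2 < eps:
                    g, sv = 0.0, 0.0
                if g < 0.0:
                    sv, g = s2, 0.0
                sv = max(sv, eps)
                num += np.log10(1.0 + g * g * s1 / (sv + sigma_nsq))
                den += np.log10(1.0 + s1 / sigma_nsq)
    return float(num / den) if den != 0.0 else 1.0


def _valid_conv_loop(img: np.ndarray, kern: np.ndarray) -> np.ndarray:
    n = kern.shape[0]
    h, w = img.shape
    out = np.empty((h - n + 1, w - n + 1))
    for i in range(h - n + 1):
        for j in range(w - n + 1):
            out[i, j] = (kern * img[i : i + n, j : j + n]).sum()
    return out


def fuse_details_oracle(
    dA: np.ndarray,
    dB: np.ndarray,
    gauss_w: int,
    gauss_sigma: float,
    wls_lambda: float,
    act_sigma: float,
    act_eps: float,
) -> np.ndarray:
    """Scalar-by-scalar evaluation of the detail-fusion steps."""
    h, w = dA.shape
    m = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            m[i, j] = 1.0 if abs(dA[i, j]) < abs(dB[i, j]) else 0.0
    g = gaussian_conv_oracle(m, gauss_w, gauss_sigma)
    prelim = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            prelim[i, j] = (1.0 - g[i, j]) * dA[i, j] + g[i, j] * dB[i, j]
    if wls_lambda == 0.0:
        return prelim
    energy = gaussian_conv_oracle(np.abs(dA), gauss_w, act_sigma)
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            a = 1.0 / (energy[i, j] + act_eps)
            out[i, j] = prelim[i, j] / (1.0 + wls_lambda * a)
    return out
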