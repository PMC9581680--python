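# Methods

## Pipeline model and assumptions

The pipeline fuses exactly two co-registered, same-size 2-D images.
Registration and resampling are out of scope: the method assumes the
inputs align pixel-for-pixel, as curated atlas pairs do. All internal
computation uses float64 on a nominal [0,1] intensity scale; images are
only quantised (8-bit, round-half-away-from-zero) and clipped at write
time, never inside the pipeline.

For a pseudo-colour functional input, fusion operates on its full-range
BT.601 luminance; the chroma planes are carried through untouched and
re-attached at the end. BT.601 was chosen because it is the standard
luma/chroma split for pseudo-colour medical display, is exactly
invertible in floating point, and fixes the gray axis (R=G=B maps to
neutral chroma). Other splits (YUV, IHS) would change the luminance
weighting slightly; nothing downstream depends on the specific choice.

## Filters

**Adaptive Wiener filter.** out = μ + m/(m+ε)(I−μ) with windowed mean μ
and variance m. The variance is clamped at zero to absorb
floating-point negatives. Two defaults exist on purpose: ε = 0.05 for
standalone use and ε = 0.01 inside the rolling-guidance loop, where a
lighter floor removes less signal before edge recovery. The window
radius is r = 3. These magnitudes are meaningful only because the
intensity scale is [0,1]: local variances of natural-image windows are
then of order 1e-3..1e-1, so ε sits in the middle of that range and
acts as a soft texture/structure threshold.

**Border handling.** Every windowed statistic (box mean, Wiener,
guided filter) divides window sums by the per-pixel count of in-image
neighbours (the box filter of an all-ones image) instead of padding.
This keeps "constant in, constant out" exact at borders and makes the
per-pixel brute-force oracles in the tests exact to 1e-12.

**Guided filter.** The standard local-linear-model form; radius is
round(σ_s) and the regulariser is σ_r². With σ_s = 2, σ_r = 0.05 the
defaults are radius 2, ε = 2.5e-3.

**IRGF.** One Wiener pass (structure removal), then T = 4 guided
passes where the previous iterate is the guide and the *original*
image is filtered (the standard rolling-guidance convention; the
alternative — filtering the iterate — drifts and loses the
scale-aware property). T = 0 degenerates to the plain Wiener filter.
The classic RGF (Gaussian removal pass with kernel size
2⌈2σ_s⌉+1) is included for comparison studies only.

## Multiscale decomposition

n = 4 levels with σ_s doubling per level (σ_s, 2σ_s, 4σ_s for the
three IRGF levels), σ_r held constant, and a final plain Wiener split.
Doubling is the established dyadic multiscale convention; n and the
schedule are free choices and both are exposed. The decomposition is
defined purely by differences of successive smooths, so reconstruction
is exact by construction regardless of what the filters do — this
telescoping identity is the module's central guarantee and is asserted
for every size/depth combination in the tests.

The final-level Wiener reuses the loop parameters (r = 3, ε = 0.01)
rather than the standalone ε = 0.05; the choice only shifts energy
between the base and the last detail layer and cannot affect
reconstruction.

## Saliency and base fusion

Histogram-contrast saliency: quantise to 256 levels, then
Sal(j) = Σᵢ hist(i)·|j−i| via a 256×256 distance matrix contracted
against the histogram (O(pixels + 256²)). The per-pixel map is min-max
normalised to [0,1]; without normalisation the base-fusion weights
½ ± (VSM_A − VSM_B)/2 could leave [0,1], so normalisation is a
necessary repair, not a tweak. A constant image gets the neutral map
0.5, which degrades base fusion to a plain average. Saliency is
computed from the full-resolution source images, not from base layers:
the activity measure should reflect what is conspicuous in the
original modality.

## Detail fusion

Per level: binary max-absolute selection (1 where |d_A| < |d_B|, ties
to 0 so the structural image's coefficient survives exact ties — a
deterministic rule that favours MRI/CT texture), softened by a 3×3
Gaussian (σ = 1.0; the size is a stated default, the σ a package
choice — any σ in ~0.5–1.5 gives a visually indistinguishable soft
transition), then combined as (1−G)·d_A + G·d_B. Because G stays in
[0,1], the preliminary detail is a pointwise convex combination.

The WLS step solves, per pixel, min_x (x − I_D)² + λ·a·x², giving
x* = I_D/(1 + λ·a). The activity weight a = 1/(Gauss(|d_A|, σ=2) + 1e-4)
is large where the structural detail is locally flat, so the shrinkage
suppresses detail exactly where it is most likely residual noise.
λ = 0.01 by default; λ = 0 disables the step. The closed form makes
three laws exact and testable: |x*| ≤ |I_D| pointwise, ‖x*‖₂
non-increasing in λ, and x* minimising the stated objective (verified
by ±1e-3 perturbation in the tests). The activity scale σ = 2 and the
guard 1e-4 are package choices; the guard only matters where the
structural detail is identically zero over the whole window.

## Metrics

SF, ESF, AG and CF are first-difference statistics computed on the
0–255 scale so magnitudes are comparable across 8-bit fusion reports.
Diagonal differences in ESF carry a 1/√2 step normalisation. CF is
defined as the un-halved variant of AG, hence CF = √2·AG exactly — the
two scores differ by a constant factor but are both reported for
comparability with the fusion literature. SSIM is the standard
single-scale form (11×11 Gaussian window, σ = 1.5, K1 = 0.01,
K2 = 0.03), delegated to scikit-image and cross-checked in the tests
against a direct windowed evaluation of the formula. VIF is the
pixel-domain variant: four dyadic scales of Gaussian blur +
downsample-by-2, windowed Gaussian-scale-mixture information terms
with noise variance 2 on the 0–255 scale; small images use as many
scales as fit, with a log message. For fused-vs-two-sources scoring
the reference-based metrics (SSIM, VIF) are averaged over the two
sources — a stated convention of this package, since the literature is
not uniform here.

## Synthetic phantoms

`make_pair` emulates what matters to this pipeline about a registered
MRI-PET/SPECT pair: a structural image whose information is
high-frequency (2–4 nested elliptical outlines at distinct gray levels,
a band of period-2–4 px sinusoidal texture, optional additive clipped
Gaussian noise) and a functional image whose information is smooth and
chromatic (2–3 Gaussian activity blobs through a hot-iron ramp, zero
outside the head outline — chosen because the ramp produces saturated
chroma that genuinely exercises the YCbCr round trip).
`make_gray_pair` emulates CT-MRI: a bright outer "bone" ring over a
flat interior complements the MRI-like texture. Everything is a pure
function of (size, seed, noise level) via a single seeded generator, so
regeneration is bit-identical.

What the phantoms do **not** model: anatomy, partial-volume effects,
modality-specific noise statistics (Rician MRI noise, Poisson counts),
intensity non-uniformity, or registration error. Passing tests
therefore demonstrate the algorithmic contracts (exact reconstruction,
rule algebra, determinism, texture/colour inheritance), not clinical
image quality.

## Numerical choices and degenerate inputs

- Window variance clamped at 0; WLS guard 1e-4; saliency min-max
  degeneracy mapped to the neutral 0.5 map.
- Constant images are fixed points of every filter and decompose into
  a constant base with zero details.
- Absolute-value ties in the selection map resolve to the structural
  side, deterministically.
- Images smaller than 2×2 are rejected; SSIM requires 11×11; VIF drops
  infeasible scales.
- The fused output is returned unclipped; clipping to [0,1] happens
  only at image write.

## Problem sizes

The test suite and the acceptance script run on phantoms of side
64–256 — 256 being the working resolution of the intended atlas-style
inputs — with the default 4-level decomposition throughout. The whole
suite and script complete in seconds on one CPU.

## Known limitations

- 2-D single-pair fusion only; no batch or volumetric mode.
- No registration; misaligned inputs produce ghosting, undetected.
- The ESF magnitudes reported by some fusion papers appear to use an
  undocumented normalisation well below the canonical definition used
  here; ESF values are therefore comparable within this package but
  not necessarily across publications.
- The WLS objective is a per-pixel shrinkage; it does not couple
  neighbouring pixels (no spatial smoothness term), which keeps it
  closed-form but limits its denoising power on structured noise.
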