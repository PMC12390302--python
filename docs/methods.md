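# Methods

## Fusion model

The input is a sequence of N co-registered single-channel frames
I₁…I_N ∈ [0, 1], labelled by (center wavelength [nm], exposure time
[ms]). Per frame, two per-pixel quality measures are combined
multiplicatively into a raw weight W_k = C_k · E_k:

* **Contrast** C: the absolute response of a discrete Laplacian filter.
  The stencil is the 3×3 4-neighbor kernel `[[0,1,0],[1,−4,1],[0,1,0]]`
  with symmetric (reflect) border handling; an 8-neighbor variant is
  selectable. Michelson and RMS contrast are deliberately not offered as
  weight measures — the Laplacian response is the model.
* **Exposedness** E(i) = exp(−(i − 0.5)²/2σ²) with σ = 2 by default.
  Note that σ = 2 on unit-interval intensities makes E almost flat
  (range ≈ [0.969, 1]), so contrast effectively dominates the weights;
  σ is a parameter for users who want exposedness to bite (σ ≈ 0.2 is
  the classical choice in exposure fusion).

Weights are normalised per pixel, Ŵ_k = W_k / Σₙ Wₙ. Where the total is
numerically zero (below ε = 1e−12: a pixel flat and ill-exposed in every
frame), the uniform fallback 1/N is used, so Σ_k Ŵ_k = 1 holds exactly
everywhere.

Two fusion engines consume the weights:

* **naive** — R̂ = Σₙ Ŵₙ·Iₙ, a per-pixel convex combination, hence
  bounded by the frame envelope and needing no clipping.
* **pyramid** — L{R}ₗ = Σₙ G{Ŵ}ₙ,ₗ · L{I}ₙ,ₗ: each Laplacian level of
  the result is the sum over frames of the frame's Laplacian level
  multiplied by the Gaussian-pyramid level of its normalised weight map;
  the result pyramid is collapsed and only then clipped to [0, 1].
  Intermediate levels are never clipped, and no per-level weight
  renormalisation is applied; at depth 1 both pyramids degenerate to the
  originals, so pyramid fusion coincides with naive fusion (a useful
  consistency check, asserted in the tests at 1e−9).

Orchestration supports two strategies over a (band × exposure) factorial
stack: `flat` fuses all N frames at once (default — it is the fully
specified weighted-blend path), while `two_stage` fuses each band's
exposure series first and then fuses the per-band results, covering the
"merge exposures, then fuse bands iteratively" style of processing.
Both are exposed because either could be a reasonable acquisition
post-processing order; they generally differ on real data.

## Pyramid machinery

Reduction smooths with the separable 5-tap generating kernel
[1, 4, 6, 4, 1]/16 (weights sum to 1; asserted at construction) and
decimates on the even grid, so level l+1 has shape ceil(shape_l / 2) and
odd sizes are handled without padding to powers of two. Borders use
whole-sample symmetric (mirror) extension, which preserves constant
images exactly and avoids edge darkening. Expansion inserts zeros on the
even grid of the exact parent shape and smooths with the same kernel
scaled ×2 per axis — the transpose of the reduce operator. Because each
Laplacian level stores the residual against this very expansion,
collapse reconstructs the source to floating-point round-off
(max error < 1e−10 is enforced as a property test over odd/even sizes up
to 257×257 and all feasible depths; measured ≈ 1e−16).

Default depth is floor(log₂(min(h, w))) levels (8 for 256×256, coarsest
level ~2 px), configurable; requesting more levels than the iterated
ceil-halving supports is an error that names the maximum feasible depth.

## Flat-field calibration

A capture of a uniform gray patch records illumination/detector
non-uniformity. Correction is multiplicative:
gain(p) = mean(ref)/max(ref(p), floor) with guard floor 1e−3 (caps the
gain at ~1000× and keeps it finite and positive); applying the gain to
the reference yields its own mean everywhere. Multiplicative (rather
than subtractive) correction is the standard choice for illumination
non-uniformity and preserves zero. A single reference may be applied to
all bands, or one per band. Dark-frame subtraction and linearity
calibration are out of scope.

## Synthetic phantom

The generator emulates the acquisition the method targets: a dense disk
under a diffusive layer, imaged at 10 NIR band-pass wavelengths
(CWLs 713, 736, …, 920 nm) at 10 exposures each, N = 100 frames of
256×256 px by default. The optical model is intentionally minimal — a
fixture for exercising the pipeline, not a tissue-optics claim:

* **Scene**: uniform background reflectance 0.55 with a disk of
  reflectance 0.22 and diameter 125 px centred in the frame. The disk is
  darker than the background so that the recovered object appears as a
  black spot with dipping cross-sections, matching the phenomenology the
  method reports on real data.
* **Tissue**: per band, the disk's contrast is multiplied by a
  Beer–Lambert-style transmission factor (default 0.30 → 0.80 rising
  linearly with wavelength — deeper NIR sees the disk better) and
  blurred with a Gaussian PSF (default σ 12 → 6 px falling with
  wavelength — less scatter at longer wavelengths).
* **Source × detector**: per-band relative intensity falls linearly from
  1.0 at 713 nm to 0.35 at 920 nm, making short-wavelength frames
  brighter, as NIR detector sensitivity and halogen-type illumination
  produce in practice.
* **Exposures**: times linspace(30, 650, 10) ms against a 100 ms
  reference. The shortest underexposes every band (frame mean < 0.2);
  the longest saturates ≥1% of pixels in every band. Chosen once from
  the under-to-overexposed, evenly distributed acquisition design.
* **Sensor**: shot noise ~ sqrt(signal/full-well) with full-well 10⁴,
  plus additive Gaussian read noise (sd 0.01), then clipping to [0, 1].
  All randomness flows from one seeded generator; a fixed seed gives a
  bit-identical stack.
* **White-light proxy**: a frame with 1% of the disk contrast and 4× the
  strongest scatter blur stands in for a visible-light view in which the
  object is invisible (synthetic; no RGB data is modelled).

What the phantom does *not* emulate: real tissue optical constants,
spatially varying illumination, registration error between frames,
specular reflections, and wavelength-dependent speckle. Passing tests on
the phantom therefore demonstrate the correctness and the qualitative
behaviour of the fusion machinery (hidden object invisible in the proxy,
faint in single frames, clear after fusion), not clinical performance.

## Detectability metrics

Cross-sections return full pixel rows/columns at a stated 0-based
(row, col); row indexes the vertical (Y) axis, col the horizontal (X)
axis, and ROIs are half-open rectangles. Detectability is quantified as
CNR = |mean(img over mask) − mean(img over background)| / sd(background)
— invariant under positive affine intensity maps; a Michelson-style
region contrast is available as an alternative. CNR is undefined (an
error) when the background is constant.

One subtlety: on frames whose background is almost entirely clipped at
the saturation rail, sd(background) measures clipping rather than noise
and the CNR diverges (≈10³ on the default phantom's most saturated
frames, versus ≈12 for the best well-exposed frame). The headline
property test — fused CNR ≥ 0.9 × the best single-frame CNR, and fused
CNR far above the white-light proxy — therefore takes the single-frame
maximum over *noise-referenced* frames, defined as frames with <1% of
background pixels at the clip rail. The 0.9 slack acknowledges that
strict dominance over every individual frame is not mathematically
guaranteed by a weighted average.

## Numerical and I/O choices

* All arithmetic in float64; file output as float32 TIFF.
* Integer input frames are normalised by the dtype maximum, never by the
  per-image range, so exposure relationships between frames survive
  loading (per-image min/max scaling would destroy the meaning of the
  exposedness weight).
* Naming convention `band{cwl}nm_exp{ms}ms.tiff` for directory stacks; a
  JSON manifest overrides it for foreign data; multi-page TIFFs carry
  the label table as JSON in the page description.
* Pipeline runs append one JSON line per stage to `run_log.jsonl`,
  enough to reproduce the run; reruns with the same config and seed are
  byte-identical.

## Problem sizes

The test suite and the acceptance script use the default 256×256,
100-frame phantom for end-to-end checks (a few seconds on one core),
reduced 64×64 scenes for I/O and pipeline tests, and fuzzed images up to
257×257 for the pyramid reconstruction property.

## Known limitations

* Frames are assumed co-registered; no alignment is performed.
* The exposedness default σ = 2 is nearly inert (see above); it is kept
  as the model's stated default rather than silently replaced.
* `two_stage` requires a complete factorial stack and refuses anything
  else at validation time.
* CNR depends on a ground-truth mask; no automatic segmentation is
  provided.
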