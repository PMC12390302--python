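# nirfuse

Multispectral NIR multi-exposure image fusion for imaging through
scattering tissue.

Near-infrared light penetrates biological tissue far deeper than visible
light, so a dense object (e.g. a tumor phantom) hidden under a diffusive
layer leaves a faint signature in NIR band-pass images even when it is
invisible to an ordinary camera. No single band/exposure shows it
clearly: each wavelength interacts differently with the tissue, and the
source/detector response makes some bands dark and others saturated.
`nirfuse` recovers the hidden object by fusing a stack of co-registered
frames — several band-pass wavelengths, each captured at several
exposures — into one well-exposed, high-contrast image.

## Method

Given frames *I₁ … I_N* in [0, 1], each frame gets a per-pixel quality
weight combining two measures:

* **contrast** *C* = |Laplacian-filtered image| (large on edges and
  texture, zero on flat regions), and
* **exposedness** *E* = exp(−(i − 0.5)² / 2σ²), a Gaussian preference
  for mid-gray over under-/overexposed intensities (σ = 2 by default).

Raw weights *W_k = C_k · E_k* are normalised across the stack,
*Ŵ_k = W_k / Σₙ Wₙ*, so they sum to one at every pixel. A naive fusion
is then the per-pixel convex combination *R̂ = Σₙ Ŵₙ · Iₙ*, but rapidly
fluctuating weights leave visible stitch lines. The seam-free variant
blends in the multi-scale domain: every level of the fused Laplacian
pyramid is

  L{R}ₗ = Σₙ G{Ŵ}ₙ,ₗ · L{I}ₙ,ₗ

(the frame's Laplacian level weighted by the Gaussian pyramid of its
weight map), and collapsing L{R} yields the final image. No HDR radiance
estimate is involved. Both a single flat fusion over all N frames and a
two-stage variant (exposures within each band first, then across bands)
are provided.

Because real acquisitions of this kind are rarely shareable, the package
includes a synthetic phantom generator reproducing the acquisition
design — a dense disk (~125 px across) under a diffusive layer, imaged
at 10 NIR bands (CWLs 713–920 nm) × 10 exposures from underexposed to
saturated, with per-band scatter blur, contrast attenuation, source
intensity roll-off, and sensor noise — plus ground truth for
detectability metrics (contrast-to-noise ratio against the disk mask)
and cross-section profiles.

## Worked example

```python
import nirfuse as nf

scene = nf.default_scene(seed=0)            # 10 bands x 10 exposures, 256x256
stack, truth = nf.generate_stack(scene)
result = nf.fuse_stack(stack, mode="pyramid", strategy="flat")

proxy = nf.white_light_proxy(scene)         # what a visible-light camera sees
print(nf.cnr(result.fused, truth.mask))     # 11.50
print(nf.cnr(proxy, truth.mask))            # 0.07
```

Output for this configuration:

```
stack: 100 frames = 10 bands x 10 exposures, 256x256 px
fused with depth=8, pre-clip range [0.357, 0.592]
CNR fused: 11.50
CNR white-light proxy: 0.07
profile dip: min 0.362 vs background mean 0.563
```

The disk is essentially undetectable in the white-light proxy
(CNR ≈ 0.07) but stands out clearly after fusion (CNR ≈ 11.5); the
cross-section through the image centre dips from the ~0.56 background to
~0.36 over roughly one disk diameter — the "black spot" the method is
designed to reveal.

The same pipeline is available from the shell:

```bash
nirfuse phantom --seed 0 --out acq/
nirfuse fuse --input acq/ --mode pyramid --strategy flat --output fused.tiff
nirfuse profile --input fused.tiff --row 128 --col 128 \
    --mask acq/truth_mask.png --out report.json
```

or end to end via `nirfuse pipeline --config config.yaml --out run/`,
which logs every stage to `run/run_log.jsonl`.

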