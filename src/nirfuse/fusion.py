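"""Fusion engines for multi-band, multi-exposure NIR stacks.

Two modes are provided:

* ``naive`` — per-pixel convex combination of the frames with the
  normalised weights,  R = sum_n W_hat_n * I_n.
* ``pyramid`` — seam-free blending: each Laplacian-pyramid level of the
  fused image is the weighted sum, over frames, of the frame's Laplacian
  level with the Gaussian-pyramid level of its normalised weight map,

      L{R}_l = sum_n G{W_hat}_n,l * L{I}_n,l,

  after which the pyramid is collapsed.  Blending weights at coarse
  scales suppresses the visible stitch lines the naive average produces
  where weights fluctuate rapidly.

Two orchestration strategies cover the acquisition design (10 bands x
10 exposures, N = 100): ``flat`` fuses all N frames in one pass;
``two_stage`` first fuses the exposure series within each band, then
fuses the per-band results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .pyramid import Pyramid, build_gaussian, build_laplacian, collapse, default_depth
from .weights import DEFAULT_SIGMA, WeightStack, compute_weight_stack

__all__ = ["FrameLabel", "ImageStack", "FusionResult", "fuse_naive", "fuse_pyramid", "fuse_stack"]


class FrameLabel(NamedTuple):
    """(center wavelength [nm], exposure time [ms]) of one frame."""

    center_wavelength_nm: float
    exposure_time_ms: float


@dataclass
class ImageStack:
    """Ordered, co-registered single-channel frames with band/exposure labels."""

    frames: np.ndarray  # (N, h, w) float array
    labels: list[FrameLabel]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(f"frames must be a nonempty (N, h, w) array, got {self.frames.shape}")
        self.labels = [FrameLabel(*lbl) for lbl in self.labels]
        if len(self.labels) != self.frames.shape[0]:
            raise ValueError(
                f"{self.frames.shape[0]} frames but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def band_cwls(self) -> list[float]:
        seen: dict[float, None] = {}
        for lbl in self.labels:
            seen.setdefault(lbl.center_wavelength_nm, None)
        return list(seen)

    @property
    def n_bands(self) -> int:
        return len(self.band_cwls)

    @property
    def n_exposures(self) -> int:
        return len({lbl.exposure_time_ms for lbl in self.labels})

    def is_factorial(self) -> bool:
        """True when every band carries the same full set of exposures."""
        by_band: dict[float, set[float]] = {}
        for lbl in self.labels:
            by_band.setdefault(lbl.center_wavelength_nm, set()).add(lbl.exposure_time_ms)
        sets = list(by_band.values())
        return (
            all(s == sets[0] for s in sets)
            and sum(len(s) for s in sets) == len(self)
        )

    def select(self, idx: list[int]) -> "ImageStack":
        return ImageStack(self.frames[idx], [self.labels[i] for i in idx])


@dataclass
class FusionResult:
    """Fused image with provenance of how it was produced."""

    fused: np.ndarray  # clipped to [0, 1]
    mode: str  # "naive" | "pyramid"
    strategy: str  # "flat" | "two_stage"
    depth: int
    provenance: dict = field(default_factory=dict)


def _check_alignment(stack: ImageStack, wstack: WeightStack) -> None:
    if wstack.n_images != len(stack):
        raise ValueError(
            f"stack has {len(stack)} frames but weight stack has {wstack.n_images}"
        )
    if any(w.shape != stack.shape for w in wstack.normalized):
        raise ValueError("weight maps do not match frame dimensions")


def _provenance(stack: ImageStack, wstack: WeightStack, pre_clip: np.ndarray) -> dict:
    return {
        "labels": [tuple(lbl) for lbl in stack.labels],
        "sigma": wstack.sigma,
        "laplacian_kernel": wstack.laplacian_kernel,
        "pre_clip_min": float(pre_clip.min()),
        "pre_clip_max": float(pre_clip.max()),
    }


def fuse_naive(stack: ImageStack, wstack: WeightStack) -> FusionResult:
    """Per-pixel weighted average of the frames (no pyramid blending).

    Since the normalised weights sum to one and the frames lie in [0, 1],
    the output is a convex combination bounded per pixel by the frame
    min/max; clipping is a no-op up to round-off.
    """
    _check_alignment(stack, wstack)
    fused = np.zeros(stack.shape, dtype=np.float64)
    for frame, w in zip(stack.frames, wstack.normalized):
        fused += w * frame
    prov = _provenance(stack, wstack, fused)
    return FusionResult(np.clip(fused, 0.0, 1.0), "naive", "flat", 1, prov)


def fuse_pyramid(stack: ImageStack, wstack: WeightStack, depth: int | None = None) -> FusionResult:
    """Laplacian-pyramid blended fusion.

    At ``depth=1`` both pyramids degenerate to the image itself, so the
    result coincides with :func:`fuse_naive`.
    """
    _check_alignment(stack, wstack)
    h, w = stack.shape
    if depth is None:
        depth = default_depth(h, w)
    fused_levels: list[np.ndarray] | None = None
    for frame, wmap in zip(stack.frames, wstack.normalized):
        gw = build_gaussian(wmap, depth)
        li = build_laplacian(frame, depth)
        if fused_levels is None:
            fused_levels = [gw[l] * li[l] for l in range(depth)]
        else:
            for l in range(depth):
                fused_levels[l] += gw[l] * li[l]
    fused = collapse(Pyramid("laplacian", fused_levels))
    prov = _provenance(stack, wstack, fused)
    return FusionResult(np.clip(fused, 0.0, 1.0), "pyramid", "flat", depth, prov)


def _fuse_once(
    stack: ImageStack,
    sigma: float,
    depth: int | None,
    mode: str,
    laplacian_kernel: str,
) -> FusionResult:
    wstack = compute_weight_stack(stack, sigma=sigma, laplacian_kernel=laplacian_kernel)
    if mode == "naive":
        return fuse_naive(stack, wstack)
    if mode == "pyramid":
        return fuse_pyramid(stack, wstack, depth)
    raise ValueError(f"unknown fusion mode {mode!r}")


def fuse_stack(
    stack: ImageStack,
    sigma: float = DEFAULT_SIGMA,
    depth: int | None = None,
    mode: str = "pyramid",
    strategy: str = "flat",
    laplacian_kernel: str = "4-neighbor",
) -> FusionResult:
    """Orchestrate weight computation and fusion over a (band x exposure) stack.

    strategy="flat"
        One fusion over all N frames (the fully specified weighted-blend
        path; default).
    strategy="two_stage"
        Fuse each band's exposure series first, then fuse the per-band
        results; requires a complete factorial stack.
    """
    if strategy == "flat":
        result = _fuse_once(stack, sigma, depth, mode, laplacian_kernel)
    elif strategy == "two_stage":
        if not stack.is_factorial():
            raise ValueError(
                "two_stage fusion requires a complete factorial (band x exposure) stack"
            )
        band_results = []
        for cwl in stack.band_cwls:
            idx = [i for i, lbl in enumerate(stack.labels) if lbl.center_wavelength_nm == cwl]
            sub = stack.select(idx)
            band_results.append(_fuse_once(sub, sigma, depth, mode, laplacian_kernel))
        band_stack = ImageStack(
            np.stack([r.fused for r in band_results]),
            [FrameLabel(cwl, float("nan")) for cwl in stack.band_cwls],
        )
        result = _fuse_once(band_stack, sigma, depth, mode, laplacian_kernel)
    else:
        raise ValueError(f"unknown fusion strategy {strategy!r}")
    result.strategy = strategy
    result.provenance.update(
        {
            "labels": [tuple(lbl) for lbl in stack.labels],
            "mode": mode,
            "strategy": strategy,
            "n_bands": stack.n_bands,
            "n_exposures": stack.n_exposures,
        }
    )
    return result
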