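"""Per-pixel quality weights for exposure fusion.

Each frame of the acquisition gets a raw weight map

    W_k = C_k * E_k

where C is the magnitude of a Laplacian-filter response (rewarding edges
and texture) and E is a Gaussian "well-exposedness" score centred on
mid-gray,

    E(i) = exp(-(i - 0.5)^2 / (2 sigma^2)),

with sigma defaulting to 2.  Raw weights are then normalised across the
stack so they sum to one at every pixel.  Note that sigma = 2 on [0, 1]
intensities makes E nearly flat (range about [0.969, 1]), so in practice
the contrast term dominates; the width is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

__all__ = [
    "DEFAULT_SIGMA",
    "LAPLACIAN_KERNELS",
    "WeightStack",
    "contrast_weight",
    "exposedness_weight",
    "combine_weights",
    "normalize_weights",
    "compute_weight_stack",
]

DEFAULT_SIGMA = 2.0

#: Selectable discrete Laplacian stencils (3x3).
LAPLACIAN_KERNELS = {
    "4-neighbor": np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64),
    "8-neighbor": np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=np.float64),
}

#: Guard against division by zero when every frame has zero weight at a pixel.
_EPS = 1e-12

# Rec.601 luma coefficients, used only if a colour frame slips in.
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {arr.shape}")
    return arr


def contrast_weight(img: np.ndarray, kernel: str = "4-neighbor") -> np.ndarray:
    """Absolute Laplacian-filter response per pixel (reflect border).

    Zero on flat regions, large on edges and texture.
    """
    arr = _to_gray(img)
    try:
        k = LAPLACIAN_KERNELS[kernel]
    except KeyError:
        raise ValueError(
            f"unknown Laplacian kernel {kernel!r}; choose from {sorted(LAPLACIAN_KERNELS)}"
        ) from None
    return np.abs(convolve(arr, k, mode="reflect"))


def exposedness_weight(img: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Gaussian closeness-to-mid-gray score, maximal (=1) at intensity 0.5."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    arr = _to_gray(img)
    return np.exp(-((arr - 0.5) ** 2) / (2.0 * sigma**2))


def combine_weights(contrast: np.ndarray, exposedness: np.ndarray) -> np.ndarray:
    """Element-wise product of the two quality measures."""
    c = np.asarray(contrast, dtype=np.float64)
    e = np.asarray(exposedness, dtype=np.float64)
    if c.shape != e.shape:
        raise ValueError(f"weight grids differ in shape: {c.shape} vs {e.shape}")
    return c * e


def normalize_weights(raw: list[np.ndarray]) -> list[np.ndarray]:
    """Divide each raw weight map by the per-pixel sum over the stack.

    Pixels where the total weight is (numerically) zero — flat and
    ill-exposed in every frame — fall back to the uniform weight 1/N, so
    the output always sums to exactly one per pixel.
    """
    if len(raw) == 0:
        raise ValueError("cannot normalize an empty weight stack")
    grids = [np.asarray(g, dtype=np.float64) for g in raw]
    shape = grids[0].shape
    if any(g.shape != shape for g in grids):
        raise ValueError("weight grids differ in shape")
    total = np.sum(grids, axis=0)
    n = len(grids)
    degenerate = total < _EPS
    safe_total = np.where(degenerate, 1.0, total)
    return [np.where(degenerate, 1.0 / n, g / safe_total) for g in grids]


@dataclass
class WeightStack:
    """Raw and normalised per-frame weight maps aligned to an image stack."""

    raw: list[np.ndarray]
    normalized: list[np.ndarray]
    sigma: float = DEFAULT_SIGMA
    laplacian_kernel: str = "4-neighbor"

    @property
    def n_images(self) -> int:
        return len(self.raw)

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.normalized) or len(self.raw) < 1:
            raise ValueError("raw and normalized weight lists must align and be nonempty")


def compute_weight_stack(
    frames,
    sigma: float = DEFAULT_SIGMA,
    laplacian_kernel: str = "4-neighbor",
) -> WeightStack:
    """Full weight pipeline over a stack of co-registered frames.

    ``frames`` may be an :class:`~nirfuse.fusion.ImageStack` or any
    sequence of equally sized 2-D arrays.
    """
    arrs, labels = _frames_and_labels(frames)
    if len(arrs) == 0:
        raise ValueError("empty image stack")
    shape = arrs[0].shape
    bad = [str(labels[i]) for i, a in enumerate(arrs) if a.shape != shape]
    if bad:
        raise ValueError(f"frames are not co-registered; offending frames: {', '.join(bad)}")
    raw = [
        combine_weights(contrast_weight(a, laplacian_kernel), exposedness_weight(a, sigma))
        for a in arrs
    ]
    return WeightStack(
        raw=raw,
        normalized=normalize_weights(raw),
        sigma=sigma,
        laplacian_kernel=laplacian_kernel,
    )


def _frames_and_labels(frames):
    """Accept an ImageStack-like object or a plain sequence of arrays."""
    if hasattr(frames, "frames") and hasattr(frames, "labels"):
        arrs = [np.asarray(f, dtype=np.float64) for f in frames.frames]
        labels = list(frames.labels)
    else:
        arrs = [np.asarray(f, dtype=np.float64) for f in frames]
        labels = [f"frame[{i}]" for i in range(len(arrs))]
    return arrs, labels
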