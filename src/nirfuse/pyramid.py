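"""Gaussian and Laplacian image pyramids with exact collapse.

The Laplacian pyramid stores, at each level, the residual between a
Gaussian-pyramid level and the interpolated version of the next-coarser
level.  Because the residual is defined against the *actual* upsampling
operator used here, collapsing the pyramid reconstructs the source image
to floating-point round-off for arbitrary (including odd) dimensions.

Conventions
-----------
* Level 0 is full resolution; level ``l+1`` has shape
  ``(ceil(h/2), ceil(w/2))`` of level ``l``.
* Smoothing uses the separable 5-tap Burt–Adelson generating kernel
  ``[1, 4, 6, 4, 1] / 16`` with mirror (whole-sample symmetric) border
  handling, which preserves constant images exactly.
* Upsampling is zero insertion on the even grid followed by the same
  kernel scaled by 2 per axis (the transpose of the reduce operator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "BURT_ADELSON_KERNEL",
    "Pyramid",
    "smooth_downsample",
    "upsample_to",
    "build_gaussian",
    "build_laplacian",
    "collapse",
    "max_feasible_depth",
    "default_depth",
]


def _make_kernel(a: float = 0.375) -> np.ndarray:
    """Classic 5-tap generating kernel ``[1/4 - a/2, 1/4, a, 1/4, 1/4 - a/2]``.

    ``a = 0.375`` gives the standard ``[1, 4, 6, 4, 1] / 16``.
    """
    k = np.array([0.25 - a / 2, 0.25, a, 0.25, 0.25 - a / 2], dtype=np.float64)
    if not np.isclose(k.sum(), 1.0, atol=1e-15):
        raise ValueError("pyramid kernel must sum to 1")
    return k


BURT_ADELSON_KERNEL = _make_kernel()


@dataclass
class Pyramid:
    """Multi-level image representation.

    Parameters
    ----------
    variant
        ``"gaussian"`` (low-pass levels) or ``"laplacian"`` (band-pass
        residuals plus a low-pass residue at the coarsest level).
    levels
        Ordered list of 2-D float arrays; ``levels[0]`` is full resolution.
    """

    variant: str
    levels: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.variant not in ("gaussian", "laplacian"):
            raise ValueError(f"unknown pyramid variant {self.variant!r}")
        if len(self.levels) < 1:
            raise ValueError("pyramid needs at least one level")

    @property
    def depth(self) -> int:
        return len(self.levels)

    def __getitem__(self, l: int) -> np.ndarray:
        return self.levels[l]


def _as_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def _smooth(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Separable smoothing; axes of length 1 are left untouched
    (mirror extension of a single sample is the sample itself)."""
    out = img
    for axis in (0, 1):
        if out.shape[axis] > 1:
            out = correlate1d(out, kernel, axis=axis, mode="mirror")
    return out


def smooth_downsample(img: np.ndarray, kernel: np.ndarray = BURT_ADELSON_KERNEL) -> np.ndarray:
    """Low-pass filter then decimate by two along each axis.

    Output shape is ``(ceil(h/2), ceil(w/2))``; a 1x1 input is returned
    as a copy (smoothing a single pixel is the identity).
    """
    arr = _as_image(img)
    if arr.shape == (1, 1):
        return arr.copy()
    return _smooth(arr, kernel)[::2, ::2]


def upsample_to(
    img: np.ndarray,
    target_h: int,
    target_w: int,
    kernel: np.ndarray = BURT_ADELSON_KERNEL,
) -> np.ndarray:
    """Interpolate ``img`` up to ``(target_h, target_w)``.

    The target must be the shape of the parent level, i.e. the input shape
    must equal ``(ceil(target_h/2), ceil(target_w/2))``.  Zero insertion on
    the even grid followed by the doubled smoothing kernel makes this the
    exact transpose of :func:`smooth_downsample`, so constants are
    preserved and the pyramid collapse identity holds.
    """
    arr = _as_image(img)
    exp_h, exp_w = -(-target_h // 2), -(-target_w // 2)
    if arr.shape != (exp_h, exp_w):
        raise ValueError(
            f"cannot upsample {arr.shape} to ({target_h}, {target_w}); "
            f"expected input shape ({exp_h}, {exp_w})"
        )
    out = np.zeros((target_h, target_w), dtype=np.float64)
    out[::2, ::2] = arr
    for axis, tlen in ((0, target_h), (1, target_w)):
        if tlen > 1:
            out = correlate1d(out, kernel * 2.0, axis=axis, mode="mirror")
    return out


def max_feasible_depth(h: int, w: int) -> int:
    """Number of levels until the coarsest reaches 1 pixel on the short side."""
    d = 1
    s = min(h, w)
    while s > 1:
        s = -(-s // 2)
        d += 1
    return d


def default_depth(h: int, w: int) -> int:
    """Default pyramid depth: ``floor(log2(min(h, w)))`` levels (>= 1),
    leaving the coarsest level about 2 px on the short side."""
    return max(1, int(np.floor(np.log2(min(h, w)))))


def _check_depth(arr: np.ndarray, depth: int) -> None:
    if depth < 1:
        raise ValueError("depth must be >= 1")
    maxd = max_feasible_depth(*arr.shape)
    if depth > maxd:
        raise ValueError(
            f"depth {depth} infeasible for image {arr.shape}; maximum feasible depth is {maxd}"
        )


def build_gaussian(
    img: np.ndarray, depth: int, kernel: np.ndarray = BURT_ADELSON_KERNEL
) -> Pyramid:
    """Gaussian pyramid: repeated smooth-and-halve starting at the image."""
    arr = _as_image(img)
    _check_depth(arr, depth)
    levels = [arr.copy()]
    for _ in range(depth - 1):
        levels.append(smooth_downsample(levels[-1], kernel))
    return Pyramid("gaussian", levels)


def build_laplacian(
    img: np.ndarray, depth: int, kernel: np.ndarray = BURT_ADELSON_KERNEL
) -> Pyramid:
    """Laplacian pyramid: band-pass residuals, coarsest level is the low-pass residue.

    Residual levels may be negative or exceed 1; only the final fused
    output of the pipeline is clipped back to [0, 1].
    """
    g = build_gaussian(img, depth, kernel)
    levels: list[np.ndarray] = []
    for l in range(depth - 1):
        up = upsample_to(g[l + 1], *g[l].shape, kernel=kernel)
        levels.append(g[l] - up)
    levels.append(g[depth - 1].copy())
    return Pyramid("laplacian", levels)


def collapse(pyr: Pyramid, kernel: np.ndarray = BURT_ADELSON_KERNEL) -> np.ndarray:
    """Reconstruct the image a Laplacian pyramid encodes.

    Upsamples the coarsest level and adds successive residuals down to
    level 0.  The result is *not* clipped; clipping is the fusion
    pipeline's final step.
    """
    if pyr.variant != "laplacian":
        raise ValueError("collapse is defined only for Laplacian pyramids")
    out = pyr.levels[-1].copy()
    for l in range(pyr.depth - 2, -1, -1):
        out = upsample_to(out, *pyr.levels[l].shape, kernel=kernel) + pyr.levels[l]
    return out
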