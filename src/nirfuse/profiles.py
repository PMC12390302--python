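"""Cross-section intensity profiles and detectability metrics.

Coordinates are 0-based; ``row`` indexes the vertical (Y) axis and
``col`` the horizontal (X) axis.  Regions of interest are half-open
rectangles ``(row0, col0, row1, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProfileReport", "cross_section", "cnr", "michelson_contrast", "zoom_roi"]


@dataclass
class ProfileReport:
    """Row/column intensity traces at a stated location, with summary stats."""

    row: int
    col: int
    row_profile: np.ndarray  # the full pixel row (length = image width)
    col_profile: np.ndarray  # the full pixel column (length = image height)
    depth_stats: dict = field(default_factory=dict)
    cnr: float | None = None
    roi: tuple[int, int, int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "col": self.col,
            "row_profile": [float(v) for v in self.row_profile],
            "col_profile": [float(v) for v in self.col_profile],
            "depth_stats": self.depth_stats,
            "cnr": self.cnr,
            "roi": list(self.roi) if self.roi is not None else None,
        }


def _stats(trace: np.ndarray) -> dict:
    return {"min": float(trace.min()), "max": float(trace.max()), "mean": float(trace.mean())}


def cross_section(img: np.ndarray, row: int, col: int) -> ProfileReport:
    """Extract the full pixel row ``row`` and column ``col`` of the image."""
    arr = np.asarray(img, dtype=np.float64)
    h, w = arr.shape
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"cross-section ({row}, {col}) outside image of shape {arr.shape}")
    rp = arr[row, :].copy()
    cp = arr[:, col].copy()
    return ProfileReport(
        row=row,
        col=col,
        row_profile=rp,
        col_profile=cp,
        depth_stats={"row": _stats(rp), "col": _stats(cp)},
    )


def cnr(img: np.ndarray, mask: np.ndarray) -> float:
    """Contrast-to-noise ratio of the masked region against the background.

        CNR = |mean(img[mask]) - mean(img[~mask])| / sd(img[~mask])

    Invariant under affine intensity transforms with positive scale.
    """
    arr = np.asarray(img, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise ValueError(f"mask shape {m.shape} does not match image shape {arr.shape}")
    fg = arr[m]
    bg = arr[~m]
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both the mask region and the background must be nonempty")
    sd = bg.std()
    if sd == 0:
        raise ValueError("background has zero standard deviation; CNR undefined")
    return float(abs(fg.mean() - bg.mean()) / sd)


def michelson_contrast(img: np.ndarray, mask: np.ndarray) -> float:
    """Alternative detectability metric: (max - min) / (max + min) of the
    two region means."""
    arr = np.asarray(img, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise ValueError("mask shape does not match image shape")
    a, b = arr[m].mean(), arr[~m].mean()
    hi, lo = max(a, b), min(a, b)
    if hi + lo == 0:
        raise ValueError("Michelson contrast undefined for zero total intensity")
    return float((hi - lo) / (hi + lo))


def zoom_roi(img: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    """Copy of the half-open rectangle ``(row0, col0, row1, col1)``."""
    arr = np.asarray(img)
    r0, c0, r1, c1 = roi
    h, w = arr.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi} is empty or outside image of shape {arr.shape}")
    return arr[r0:r1, c0:c1].copy()
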