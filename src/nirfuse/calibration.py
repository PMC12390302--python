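"""Flat-field correction from a gray uniform patch.

A capture of a uniform gray patch records the combined spatial
non-uniformity of illumination and detector response.  The correction is
multiplicative: each pixel is scaled by ``mean(reference) / reference(p)``
so that the reference itself maps to a constant frame.  A guard floor
caps the gain where the reference is nearly black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FlatField", "build_flat_field", "apply_flat_field", "DEFAULT_FLOOR"]

#: Default guard floor on [0, 1] intensities; caps gain at ~1000x.
DEFAULT_FLOOR = 1e-3


@dataclass
class FlatField:
    """Per-pixel multiplicative gain derived from a gray-patch capture."""

    reference: np.ndarray
    gain: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.gain)) and np.all(self.gain > 0)):
            raise ValueError("flat-field gain must be finite and positive everywhere")


def build_flat_field(reference: np.ndarray, floor: float = DEFAULT_FLOOR) -> FlatField:
    """gain(p) = mean(reference) / max(reference(p), floor)."""
    ref = np.asarray(reference, dtype=np.float64)
    if ref.ndim != 2 or ref.size == 0:
        raise ValueError("reference must be a nonempty 2-D image")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    mean = float(ref.mean())
    if mean <= floor:
        raise ValueError(
            f"reference patch too dark to calibrate (mean {mean:.3g} <= floor {floor:.3g})"
        )
    gain = mean / np.maximum(ref, floor)
    return FlatField(reference=ref.copy(), gain=gain, floor=floor)


def apply_flat_field(img: np.ndarray, ff: FlatField) -> np.ndarray:
    """Multiply by the gain map and clip back to [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.shape != ff.gain.shape:
        raise ValueError(f"image shape {arr.shape} does not match flat field {ff.gain.shape}")
    return np.clip(arr * ff.gain, 0.0, 1.0)
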