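"""Synthetic scattering-tissue phantom acquisition.

Simulates imaging a dense disk ("tumor") hidden under a diffusive tissue
layer with a 10-band NIR camera (CWLs 713-920 nm) at 10 exposures per
band, N = 100 frames in total.  The optical model is deliberately
simple — a fixture for exercising the fusion pipeline, not a claim
about tissue optics:

* the scene is a uniform background reflectance with a darker disk of
  ~125 px diameter embedded under the tissue;
* the tissue attenuates the disk's contrast per band (Beer-Lambert-style
  transmission factor) and blurs it with a per-band Gaussian point-spread
  function (stronger scatter at shorter wavelengths);
* each band is scaled by a source-times-detector relative intensity that
  decreases with wavelength (frames are brighter at the short-wave end);
* each exposure multiplies the radiance by a scale spanning underexposed
  to saturated, then sensor noise (shot noise plus additive Gaussian read
  noise) is added and the frame is clipped to [0, 1].

A deterministic seed yields a bit-identical stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .fusion import FrameLabel, ImageStack

__all__ = [
    "PhantomScene",
    "GroundTruth",
    "default_scene",
    "render_band",
    "generate_stack",
    "white_light_proxy",
    "DEFAULT_CWLS_NM",
]

#: The acquisition's band-pass center wavelengths [nm].
DEFAULT_CWLS_NM = (713.0, 736.0, 759.0, 782.0, 805.0, 828.0, 851.0, 874.0, 897.0, 920.0)

#: Exposure scale corresponding to a nominal 100 ms reference exposure.
_REFERENCE_EXPOSURE_MS = 100.0


@dataclass
class PhantomScene:
    """Parametric description of the phantom and the acquisition design."""

    image_h: int = 256
    image_w: int = 256
    disk_center: tuple[int, int] = (128, 128)  # (row, col)
    disk_diameter_px: float = 125.0
    disk_reflectance: float = 0.22
    background_reflectance: float = 0.55
    band_cwls_nm: tuple[float, ...] = DEFAULT_CWLS_NM
    # source x detector relative intensity, brighter at shorter wavelengths
    band_relative_intensity: tuple[float, ...] = tuple(
        float(x) for x in np.linspace(1.0, 0.35, 10).round(6)
    )
    # diffusive-layer PSF width [px]; scatter weakens with wavelength
    scatter_sigma_px: tuple[float, ...] = tuple(
        float(x) for x in np.linspace(12.0, 6.0, 10).round(6)
    )
    # disk-contrast transmission through the tissue; deeper NIR sees more
    attenuation: tuple[float, ...] = tuple(
        float(x) for x in np.linspace(0.30, 0.80, 10).round(6)
    )
    # evenly spaced exposure times, under- to overexposed (100 ms reference)
    exposure_times_ms: tuple[float, ...] = tuple(
        float(x) for x in np.linspace(30.0, 650.0, 10).round(6)
    )
    noise_gaussian_sd: float = 0.01
    noise_poisson_scale: float = 10000.0  # effective full-well photon count
    seed: int = 0

    def __post_init__(self) -> None:
        nb = len(self.band_cwls_nm)
        for name in ("band_relative_intensity", "scatter_sigma_px", "attenuation"):
            if len(getattr(self, name)) != nb:
                raise ValueError(f"{name} must have one entry per band ({nb})")
        r = self.disk_diameter_px / 2.0
        row, col = self.disk_center
        if not (r <= row <= self.image_h - 1 - r and r <= col <= self.image_w - 1 - r):
            raise ValueError("disk must lie fully inside the frame")
        if any(t <= 0 for t in self.exposure_times_ms):
            raise ValueError("exposure times must be positive")

    @property
    def n_bands(self) -> int:
        return len(self.band_cwls_nm)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_times_ms)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomScene":
        kwargs = dict(d)
        for k in (
            "band_cwls_nm",
            "band_relative_intensity",
            "scatter_sigma_px",
            "attenuation",
            "exposure_times_ms",
        ):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        if "disk_center" in kwargs:
            kwargs["disk_center"] = tuple(kwargs["disk_center"])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Binary disk mask (1 = disk) plus an echo of the generating scene."""

    mask: np.ndarray
    scene_params: dict = field(default_factory=dict)


def default_scene(seed: int = 0) -> PhantomScene:
    """The default acquisition: 10 bands x 10 exposures, 125 px disk."""
    return PhantomScene(seed=seed)


def disk_mask(scene: PhantomScene) -> np.ndarray:
    rr, cc = np.mgrid[0 : scene.image_h, 0 : scene.image_w]
    r0, c0 = scene.disk_center
    return ((rr - r0) ** 2 + (cc - c0) ** 2) <= (scene.disk_diameter_px / 2.0) ** 2


def render_band(scene: PhantomScene, band_idx: int) -> np.ndarray:
    """Ideal (noise-free, unit-exposure) radiance image of one band.

    Background reflectance plus the disk's (negative) contrast, scaled by
    the band's tissue transmission, blurred by the scatter PSF, and
    finally scaled by the band's relative source/detector intensity.
    Deterministic given the scene.
    """
    if not 0 <= band_idx < scene.n_bands:
        raise IndexError(f"band index {band_idx} out of range [0, {scene.n_bands})")
    mask = disk_mask(scene).astype(np.float64)
    delta = (scene.disk_reflectance - scene.background_reflectance) * scene.attenuation[band_idx]
    contrast = delta * mask
    sigma = scene.scatter_sigma_px[band_idx]
    if sigma > 0:
        contrast = gaussian_filter(contrast, sigma, mode="reflect")
    radiance = scene.background_reflectance + contrast
    return radiance * scene.band_relative_intensity[band_idx]


def _sensor_frame(
    radiance: np.ndarray, exposure_scale: float, scene: PhantomScene, rng: np.random.Generator
) -> np.ndarray:
    signal = radiance * exposure_scale
    shot_sd = np.sqrt(np.maximum(signal, 0.0) / scene.noise_poisson_scale)
    noisy = (
        signal
        + rng.normal(0.0, 1.0, signal.shape) * shot_sd
        + rng.normal(0.0, scene.noise_gaussian_sd, signal.shape)
    )
    return np.clip(noisy, 0.0, 1.0)


def generate_stack(scene: PhantomScene) -> tuple[ImageStack, GroundTruth]:
    """Full factorial (band x exposure) acquisition with ground truth.

    Frames are ordered band-major, exposures increasing within each band.
    The shortest exposure underexposes every band (mean < 0.2); the
    longest saturates part of the frame.  The same seed reproduces the
    stack bit for bit.
    """
    rng = np.random.default_rng(scene.seed)
    frames = []
    labels = []
    for b in range(scene.n_bands):
        radiance = render_band(scene, b)
        for t in scene.exposure_times_ms:
            scale = t / _REFERENCE_EXPOSURE_MS
            frames.append(_sensor_frame(radiance, scale, scene, rng))
            labels.append(FrameLabel(scene.band_cwls_nm[b], t))
    stack = ImageStack(np.stack(frames), labels)
    truth = GroundTruth(mask=disk_mask(scene), scene_params=scene.to_dict())
    return stack, truth


def white_light_proxy(scene: PhantomScene) -> np.ndarray:
    """Stand-in for a visible-light (RGB) view in which the disk is invisible.

    Visible light barely penetrates the tissue, so the proxy carries
    almost no disk contrast and very strong scatter blur; sensor noise is
    drawn from an offset of the scene seed.
    """
    mask = disk_mask(scene).astype(np.float64)
    delta = (scene.disk_reflectance - scene.background_reflectance) * 0.01
    contrast = gaussian_filter(delta * mask, 4.0 * max(scene.scatter_sigma_px), mode="reflect")
    radiance = scene.background_reflectance + contrast
    rng = np.random.default_rng(scene.seed + 1_000_003)
    return _sensor_frame(radiance, 1.0, scene, rng)
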