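"""Snellen-E stimuli and their diffraction-limited retinal images.

The acuity stimulus is a dark ("off") Snellen E drawn on a uniform infrared
raster.  Its retinal image is modeled by convolving the binary decrement
bitmap with the eye's diffraction-limited point spread function — an Airy
pattern for the given wavelength and pupil diameter.  Working in decrement
space (0 = background, 1 = fully dark) makes the uniform background
implicit, so zero-padding at the convolution boundary is exact.

Contrast of the blurred stimulus is reported as Michelson contrast
(I_bg - I_min) / (I_bg + I_min) by default; Weber decrement contrast
(I_bg - I_min) / I_bg = max decrement is available via ``metric="weber"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import j1

__all__ = [
    "OpticalConfig",
    "StimulusSpec",
    "RetinalImage",
    "airy_psf",
    "airy_disk_radius",
    "airy_disk_diameter",
    "make_snellen_e",
    "retinal_image",
    "stimulus_contrast",
    "ARCSEC_PER_RADIAN",
]

ARCSEC_PER_RADIAN = 180.0 / np.pi * 3600.0
ORIENTATIONS = ("up", "down", "left", "right")


@dataclass(frozen=True)
class OpticalConfig:
    """Diffraction-limited imaging condition.

    wavelength in nm (788 or 840 in the experiments), pupil diameter in mm
    (7), pixel scale of the display raster in arcmin per pixel (0.1).
    """

    wavelength_nm: float = 788.0
    pupil_diameter_mm: float = 7.0
    pixel_scale: float = 0.1

    def __post_init__(self):
        if not (400.0 <= self.wavelength_nm <= 1000.0):
            raise ValueError("wavelength must be in [400, 1000] nm")
        if self.pupil_diameter_mm <= 0 or self.pixel_scale <= 0:
            raise ValueError("pupil diameter and pixel scale must be positive")


@dataclass(frozen=True)
class StimulusSpec:
    """Snellen-E stimulus: gap size in arcsec and opening orientation.

    The letter follows the standard 5x5 construction — stroke width = gap
    width = one fifth of letter height — and is a luminance decrement
    ("off-stimulus") on the background raster.
    """

    gap_arcsec: float
    orientation: str = "right"

    def __post_init__(self):
        if self.gap_arcsec <= 0:
            raise ValueError("gap size must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")

    @property
    def letter_height_arcsec(self) -> float:
        return 5.0 * self.gap_arcsec


@dataclass(frozen=True)
class RetinalImage:
    """Diffraction-blurred stimulus decrement map in retinal coordinates.

    ``decrement[r, c]`` in [0, 1]: 1 = full stimulus darkness relative to the
    background, 0 = undisturbed background.  ``center`` is the (x, y) arcmin
    position of the stimulus center within the map's own frame.
    """

    decrement: np.ndarray
    pixel_scale: float
    center: tuple[float, float]

    def __post_init__(self):
        d = np.asarray(self.decrement, dtype=float)
        if d.min() < -1e-9 or d.max() > 1.0 + 1e-9:
            raise ValueError("decrement values must lie in [0, 1]")
        object.__setattr__(self, "decrement", np.clip(d, 0.0, 1.0))


def airy_disk_radius(config: OpticalConfig) -> float:
    """Radius of the first Airy intensity zero, arcsec: 1.22 lambda/D."""
    lam = config.wavelength_nm * 1e-9
    d = config.pupil_diameter_mm * 1e-3
    return 1.22 * lam / d * ARCSEC_PER_RADIAN


def airy_disk_diameter(config: OpticalConfig) -> float:
    """Diameter of the first dark ring, arcsec: 2.44 lambda/D."""
    return 2.0 * airy_disk_radius(config)


def airy_psf(config: OpticalConfig, support: int | None = None) -> np.ndarray:
    """Diffraction-limited PSF sampled at the raster pixel scale.

    Rotationally symmetric Airy intensity pattern [2 J1(v)/v]^2 on an odd
    ``support`` x ``support`` pixel grid, normalized to unit sum.  The support
    must span at least 4 Airy-disk radii; the default spans ~32 radii so the
    slowly decaying rings are effectively fully captured.
    """
    radius_px = airy_disk_radius(config) / 60.0 / config.pixel_scale
    min_support = int(np.ceil(4.0 * radius_px)) | 1
    if support is None:
        support = (int(np.ceil(32.0 * radius_px)) | 1)
    if support < min_support:
        raise ValueError(
            f"PSF support of {support} px spans fewer than 4 Airy radii; "
            f"need at least {min_support} px"
        )
    t = (np.arange(support) - support // 2) * config.pixel_scale
    xx, yy = np.meshgrid(t, t)
    r_rad = np.deg2rad(np.hypot(xx, yy) / 60.0)
    v = np.pi * (config.pupil_diameter_mm * 1e-3) * r_rad \
        / (config.wavelength_nm * 1e-9)
    v = np.where(v == 0.0, 1e-300, v)
    psf = np.where(v < 1e-6, 1.0, (2.0 * j1(v) / v) ** 2)
    return psf / psf.sum()


def make_snellen_e(spec: StimulusSpec, pixel_scale: float = 0.1) -> np.ndarray:
    """Binary Snellen-E bitmap (1 inside strokes) at the given pixel scale.

    Standard 5x5 construction: three bars plus a connecting spine, with bar
    width = gap width = ``spec.gap_arcsec``.  The base letter opens to the
    right; other orientations are rigid rotations.  The gap must be at least
    one raster pixel.
    """
    gap_px = spec.gap_arcsec / 60.0 / pixel_scale
    g = int(round(gap_px))
    if g < 1 or abs(gap_px - g) > 1e-6:
        raise ValueError(
            f"gap of {spec.gap_arcsec} arcsec is {gap_px:.3f} px at "
            f"{pixel_scale} arcmin/px; needs to be a whole number >= 1"
        )
    size = 5 * g
    e = np.zeros((size, size))
    e[0:g, :] = 1.0          # top bar
    e[2 * g:3 * g, :] = 1.0  # middle bar
    e[4 * g:5 * g, :] = 1.0  # bottom bar
    e[:, 0:g] = 1.0          # spine (left) -> openings face right
    rot = {"right": 0, "up": 1, "left": 2, "down": 3}[spec.orientation]
    return np.rot90(e, rot)


def retinal_image(bitmap: np.ndarray, psf: np.ndarray,
                  pixel_scale: float = 0.1) -> RetinalImage:
    """Convolve a stimulus decrement bitmap with a normalized PSF.

    The bitmap is zero-padded by the PSF half-width so the blurred letter is
    fully contained; the result is the stimulus decrement map with the letter
    centered in its frame.
    """
    if abs(psf.sum() - 1.0) > 1e-6:
        raise ValueError("PSF must be normalized to unit sum")
    pad = psf.shape[0] // 2
    padded = np.pad(np.asarray(bitmap, dtype=float), pad)
    dec = fftconvolve(padded, psf, mode="same")
    dec = np.clip(dec, 0.0, 1.0)
    center = ((padded.shape[1] / 2.0) * pixel_scale,
              (padded.shape[0] / 2.0) * pixel_scale)
    return RetinalImage(decrement=dec, pixel_scale=pixel_scale, center=center)


def stimulus_contrast(image: RetinalImage, metric: str = "michelson") -> float:
    """Contrast of the blurred stimulus against the uniform background.

    With background intensity I_bg = 1 and the darkest stimulus point
    I_min = 1 - max(decrement):

    * ``michelson`` (default): (I_bg - I_min) / (I_bg + I_min)
    * ``weber``: (I_bg - I_min) / I_bg, i.e. the maximum decrement
    """
    dmax = float(image.decrement.max())
    if metric == "weber":
        return dmax
    if metric == "michelson":
        return dmax / (2.0 - dmax)
    raise ValueError("metric must be 'michelson' or 'weber'")
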