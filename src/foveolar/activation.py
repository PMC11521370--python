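"""Cone light-capture model: apertures, activation patterns, sampling density.

Each cone is modeled as a Gaussian light-acceptance aperture whose diameter
is 48% of the average spacing between the cone and its (Delaunay) neighbors.
The Gaussian's FWHM equals that diameter.  An activation value in [0, 1] is
computed per cone and per video frame by integrating the stimulus decrement
map over the aperture profile and normalizing by the aperture integral —
activation is 1 when the entire aperture is filled by the (fully dark)
stimulus and 0 when no stimulus light-decrement falls on it.

The task-related "sampling cone density" of a frame is the number of cones
interacting with the stimulus (activation above a small threshold) divided
by the sum of their Voronoi patch areas, in cones/deg^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from foveolar.mosaic import ARCMIN2_PER_DEG2, ConeMosaic, VoronoiPatchSet
from foveolar.optics import RetinalImage

__all__ = [
    "ConeApertureSet",
    "ActivationPattern",
    "SamplingDensitySeries",
    "build_apertures",
    "activation_pattern",
    "sampling_cone_density",
    "trial_sampling_series",
    "FWHM_TO_SIGMA",
]

#: FWHM = FWHM_TO_SIGMA * sigma for a Gaussian profile.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

APERTURE_FRACTION = 0.48


@dataclass(frozen=True)
class ConeApertureSet:
    """Gaussian acceptance apertures of a cone mosaic.

    Per cone: center (arcmin), aperture diameter (arcmin, 0.48 x mean
    Delaunay-neighbor spacing), Gaussian sigma (diameter / 2.3548, i.e.
    FWHM = diameter), and Voronoi patch area (arcmin^2).
    """

    centers: np.ndarray
    diameters: np.ndarray
    sigmas: np.ndarray
    areas: np.ndarray

    def __len__(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class ActivationPattern:
    """Per-cone activation values in [0, 1] for one stimulus frame."""

    time_ms: float
    values: np.ndarray
    stimulus_position: tuple[float, float]


@dataclass(frozen=True)
class SamplingDensitySeries:
    """Per-frame sampling cone density over a trial's stimulus window.

    Frames where no cone interacted with the stimulus are flagged undefined
    (``defined`` False, density NaN) rather than silently zero.
    """

    times_ms: np.ndarray
    densities: np.ndarray
    counts: np.ndarray
    positions: np.ndarray
    defined: np.ndarray

    @property
    def onset_density(self) -> float:
        """Sampling density at the first defined frame of the window."""
        idx = np.flatnonzero(self.defined)
        if idx.size == 0:
            raise ValueError("no defined frames in series")
        return float(self.densities[idx[0]])

    @property
    def median_density(self) -> float:
        """Median sampling density over defined frames — the trial's value."""
        d = self.densities[self.defined]
        if d.size == 0:
            raise ValueError("no defined frames in series")
        return float(np.median(d))


def build_apertures(mosaic: ConeMosaic, patches: VoronoiPatchSet,
                    aperture_fraction: float = APERTURE_FRACTION,
                    ) -> ConeApertureSet:
    """Derive per-cone Gaussian apertures from the tessellated mosaic.

    Diameter = ``aperture_fraction`` (default 0.48) times the mean distance
    from the cone to its Delaunay neighbors; Gaussian FWHM = diameter.
    """
    centers = mosaic.cone_centers
    n = len(centers)
    diameters = np.empty(n)
    for i in range(n):
        nbr = patches.neighbors[i]
        if nbr.size == 0:
            raise ValueError(f"cone {i} has no neighbors; cannot size aperture")
        d = np.linalg.norm(centers[nbr] - centers[i], axis=1)
        diameters[i] = aperture_fraction * d.mean()
    return ConeApertureSet(centers=centers, diameters=diameters,
                           sigmas=diameters / FWHM_TO_SIGMA,
                           areas=patches.areas)


def _decrement_at(image: RetinalImage, points: np.ndarray,
                  stimulus_position: tuple[float, float]) -> np.ndarray:
    """Sample the decrement map (bilinear) at mosaic-frame points, with the
    stimulus center placed at ``stimulus_position``."""
    ps = image.pixel_scale
    # map frame: stimulus center sits at image.center
    px = (points[:, 0] - stimulus_position[0] + image.center[0]) / ps - 0.5
    py = (points[:, 1] - stimulus_position[1] + image.center[1]) / ps - 0.5
    return map_coordinates(image.decrement, [py, px], order=1, mode="constant",
                           cval=0.0)


def activation_pattern(
    apertures: ConeApertureSet,
    image: RetinalImage,
    stimulus_position: tuple[float, float],
    image_extent: tuple[float, float] | None = None,
    time_ms: float = 0.0,
    supersample: int = 4,
    profile_radius_sigmas: float = 3.0,
    cone_indices: np.ndarray | None = None,
) -> ActivationPattern:
    """Cone activation pattern for one stimulus position.

    Per cone, activation = sum(aperture profile x decrement) / sum(profile),
    evaluated on a grid supersampled ``supersample``-fold relative to the
    image pixel scale and truncated at ``profile_radius_sigmas`` sigmas.
    Invariant to global rescaling of the profile by construction.

    ``image_extent`` (arcmin), when given, bounds valid stimulus placement;
    placing the stimulus outside raises ValueError.  ``cone_indices``
    restricts evaluation to a subset (others get activation 0).
    """
    if image_extent is not None:
        w, h = image_extent
        x0, y0 = stimulus_position
        if not (0.0 <= x0 <= w and 0.0 <= y0 <= h):
            raise ValueError(
                f"stimulus position {stimulus_position} outside extent {image_extent}"
            )
    n = len(apertures)
    values = np.zeros(n)
    idx = np.arange(n) if cone_indices is None else np.asarray(cone_indices)
    step = image.pixel_scale / supersample
    for i in idx:
        sigma = apertures.sigmas[i]
        r = profile_radius_sigmas * sigma
        m = max(1, int(np.ceil(r / step)))
        t = np.arange(-m, m + 1) * step
        xx, yy = np.meshgrid(t, t)
        rr2 = xx ** 2 + yy ** 2
        w_prof = np.exp(-rr2 / (2.0 * sigma ** 2))
        pts = np.column_stack([
            apertures.centers[i, 0] + xx.ravel(),
            apertures.centers[i, 1] + yy.ravel(),
        ])
        dec = _decrement_at(image, pts, stimulus_position)
        values[i] = float(np.dot(w_prof.ravel(), dec) / w_prof.sum())
    return ActivationPattern(time_ms=time_ms, values=np.clip(values, 0.0, 1.0),
                             stimulus_position=tuple(stimulus_position))


def sampling_cone_density(pattern: ActivationPattern,
                          apertures: ConeApertureSet,
                          interaction_threshold: float = 0.01,
                          ) -> tuple[float, int]:
    """Sampling cone density (cones/deg^2) and interacting-cone count.

    Cones with activation above ``interaction_threshold`` are counted as
    interacting; density = count / (sum of their Voronoi areas).  Returns
    (nan, 0) for a frame with no interacting cone — a flagged-undefined
    frame, not a zero.
    """
    mask = pattern.values > interaction_threshold
    count = int(mask.sum())
    if count == 0:
        return float("nan"), 0
    area = float(apertures.areas[mask].sum())
    return count / area * ARCMIN2_PER_DEG2, count


def trial_sampling_series(
    apertures: ConeApertureSet,
    image: RetinalImage,
    trace,
    image_extent: tuple[float, float] | None = None,
    interaction_threshold: float = 0.01,
    supersample: int = 4,
) -> SamplingDensitySeries:
    """Per-frame sampling density along a gaze trace's stimulus window.

    One density and interacting-cone count per frame inside the trace's
    stimulus-on window; the trial's scalar sampling density is the median
    over defined frames (``SamplingDensitySeries.median_density``).
    """
    t, xy = trace.window_samples()
    if len(t) == 0:
        raise ValueError("trace has no frames inside the stimulus window")
    # prefilter: only cones within stimulus footprint + aperture reach can interact
    half_diag = 0.5 * float(np.hypot(*image.decrement.shape)) * image.pixel_scale
    reach = half_diag + 4.0 * float(apertures.diameters.max())
    densities = np.empty(len(t))
    counts = np.empty(len(t), dtype=int)
    for f in range(len(t)):
        d2 = np.sum((apertures.centers - xy[f]) ** 2, axis=1)
        near = np.flatnonzero(d2 <= reach ** 2)
        pat = activation_pattern(
            apertures, image, tuple(xy[f]), image_extent=image_extent,
            time_ms=float(t[f]), supersample=supersample, cone_indices=near)
        densities[f], counts[f] = sampling_cone_density(
            pat, apertures, interaction_threshold)
    defined = counts > 0
    return SamplingDensitySeries(times_ms=np.asarray(t, dtype=float),
                                 densities=densities, counts=counts,
                                 positions=np.asarray(xy, dtype=float),
                                 defined=defined)
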