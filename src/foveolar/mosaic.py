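"""Cone-mosaic density mapping and foveolar landmarks.

A labeled cone mosaic (one coordinate per cone center) is turned into a
pixel-resolved cone-density map by Voronoi tessellation: each cone owns a
patch of retina, and the density at an image pixel is the number of nearest
cones (default 150) divided by the summed area of their patches.  From the
map we derive the landmark set used by all downstream analyses:

* PCD — peak cone density, the map maximum and its location;
* CDC — cone density centroid, the density-weighted centroid of the top-20%
  density pixels (a more robust anatomical center than the PCD);
* ICD — average inter-cone distance under a perfect-hexagonal-lattice
  assumption, ICD = sqrt(2 / (sqrt(3) * density));
* Nyquist limit — the finest resolvable half-period implied by cone row
  spacing, N = (sqrt(3)/2) * ICD.

All positions are in arcmin (origin top-left, x rightward, y downward),
areas in arcmin^2, densities in cones/deg^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree

__all__ = [
    "TessellationError",
    "ConeMosaic",
    "VoronoiPatchSet",
    "DensityMap",
    "FoveolarLandmarks",
    "tessellate",
    "density_map",
    "peak_cone_density",
    "cone_density_centroid",
    "icd_from_density",
    "nyquist_limit",
    "compute_landmarks",
    "HEX_ROW_FACTOR",
]

#: Row spacing of a hexagonal lattice relative to its inter-cone distance.
#: Used as the Nyquist-limit conversion factor N = HEX_ROW_FACTOR * ICD.
HEX_ROW_FACTOR = math.sqrt(3.0) / 2.0

ARCMIN2_PER_DEG2 = 3600.0


class TessellationError(ValueError):
    """Raised when a cone set cannot be tessellated (too few or degenerate)."""


@dataclass(frozen=True)
class ConeMosaic:
    """Cone-center coordinates on a calibrated retinal image grid.

    Parameters
    ----------
    cone_centers
        (n, 2) array of (x, y) positions in arcmin, image frame.
    image_extent
        (width, height) of the image in arcmin.
    pixel_scale
        Size of one image pixel in arcmin (default 0.1).
    """

    cone_centers: np.ndarray
    image_extent: tuple[float, float]
    pixel_scale: float = 0.1

    def __post_init__(self):
        centers = np.asarray(self.cone_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 2:
            raise ValueError("cone_centers must be an (n, 2) array")
        object.__setattr__(self, "cone_centers", centers)
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        w, h = self.image_extent
        if w <= 0 or h <= 0:
            raise ValueError("image_extent must be positive")
        if centers.size:
            if (centers[:, 0] < 0).any() or (centers[:, 0] > w).any() \
                    or (centers[:, 1] < 0).any() or (centers[:, 1] > h).any():
                raise ValueError("cone centers must lie inside image_extent")
            # coincident centers break the tessellation invariant
            _, counts = np.unique(np.round(centers, 9), axis=0, return_counts=True)
            if (counts > 1).any():
                raise ValueError("cone centers must be distinct")

    @property
    def n_cones(self) -> int:
        return len(self.cone_centers)

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the pixel grid covering the image extent."""
        w, h = self.image_extent
        return (int(round(h / self.pixel_scale)), int(round(w / self.pixel_scale)))


@dataclass(frozen=True)
class VoronoiPatchSet:
    """Per-cone Voronoi patch areas and Delaunay neighbor relations.

    ``areas`` are polygon areas in arcmin^2 after clipping boundary cells to
    the image rectangle.  ``neighbors[i]`` lists indices of Delaunay-adjacent
    cones.  ``clipped[i]`` is True where the raw Voronoi cell extended beyond
    the image rectangle (or was unbounded) and was clipped.
    """

    areas: np.ndarray
    neighbors: list[np.ndarray]
    clipped: np.ndarray
    polygons: list[np.ndarray] = field(repr=False, default=None)


def _clipped_voronoi_areas(points: np.ndarray, extent: tuple[float, float]):
    """Voronoi cell polygons clipped to [0,w]x[0,h] via boundary mirroring.

    Mirroring every point across each of the four image edges makes all cells
    of the original points finite and exactly clipped to the rectangle.
    """
    w, h = extent
    mirrored = [points]
    for axis, bound in ((0, 0.0), (0, w), (1, 0.0), (1, h)):
        m = points.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    n = len(points)
    areas = np.empty(n)
    polys: list[np.ndarray] = []
    clipped = np.zeros(n, dtype=bool)
    eps = 1e-9 * max(w, h)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:  # pragma: no cover - mirroring prevents this
            raise TessellationError(f"unbounded Voronoi cell for cone {i}")
        verts = vor.vertices[region]
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        on_edge = (x < eps) | (x > w - eps) | (y < eps) | (y > h - eps)
        clipped[i] = bool(on_edge.any())
        polys.append(verts)
    return areas, polys, clipped


def tessellate(mosaic: ConeMosaic) -> VoronoiPatchSet:
    """Voronoi-tessellate the mosaic, assigning each cone a patch area.

    Boundary cells are clipped to the image rectangle.  Requires at least 4
    non-collinear cone centers.

    Raises
    ------
    TessellationError
        For fewer than 4 cones or degenerate (collinear) input.
    """
    pts = mosaic.cone_centers
    if len(pts) < 4:
        raise TessellationError(
            f"need at least 4 cone centers to tessellate, got {len(pts)}"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise TessellationError(f"degenerate cone configuration: {exc}") from exc
    if tri.simplices.size == 0:
        raise TessellationError("degenerate (collinear) cone configuration")

    areas, polys, clipped = _clipped_voronoi_areas(pts, mosaic.image_extent)
    if (areas <= 0).any():
        raise TessellationError("zero-area Voronoi cell encountered")

    indptr, indices = tri.vertex_neighbor_vertices
    neighbors = [indices[indptr[i]:indptr[i + 1]].copy() for i in range(len(pts))]
    return VoronoiPatchSet(areas=areas, neighbors=neighbors, clipped=clipped,
                           polygons=polys)


@dataclass(frozen=True)
class DensityMap:
    """Pixel-resolved cone density (cones/deg^2) at pixel centers.

    ``values[r, c]`` is the density at pixel center
    ``x = (c + 0.5) * pixel_scale``, ``y = (r + 0.5) * pixel_scale``; the map
    may be computed on a decimated grid (``stride`` > 1), in which case pixel
    centers move accordingly.
    """

    values: np.ndarray
    pixel_scale: float
    k: int
    stride: int = 1
    origin: tuple[float, float] = (0.0, 0.0)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) 1-D coordinate arrays of the map's pixel centers, arcmin."""
        step = self.pixel_scale * self.stride
        rows, cols = self.values.shape
        x = self.origin[0] + (np.arange(cols) + 0.5) * step
        y = self.origin[1] + (np.arange(rows) + 0.5) * step
        return x, y


def density_map(
    mosaic: ConeMosaic,
    patches: VoronoiPatchSet,
    k: int = 150,
    stride: int = 1,
    margin: float = 0.0,
) -> DensityMap:
    """Nearest-k cone-density map on the (optionally decimated) pixel grid.

    For each pixel center, the k cones nearest by Euclidean center-to-center
    distance are found (ties broken by cone index) and the density is
    k / (sum of their Voronoi patch areas), converted to cones/deg^2.

    Parameters
    ----------
    k
        Neighbor count (default 150).
    stride
        Grid decimation factor for speed; 1 = full pixel grid.
    margin
        Optional edge margin in arcmin excluded from the map on every side.
    """
    if mosaic.n_cones < k:
        raise ValueError(
            f"mosaic has {mosaic.n_cones} cones; need >= k={k}. "
            "Use a smaller k."
        )
    step = mosaic.pixel_scale * stride
    w, h = mosaic.image_extent
    x = np.arange(margin, w - margin - 1e-12, step) + 0.5 * step
    y = np.arange(margin, h - margin - 1e-12, step) + 0.5 * step
    tree = cKDTree(mosaic.cone_centers)
    values = np.empty((len(y), len(x)))
    # chunk rows to bound the (npix, k) index workspace
    chunk = max(1, int(2e6 / max(k, 1) / max(len(x), 1)))
    for r0 in range(0, len(y), chunk):
        yy = y[r0:r0 + chunk]
        gx, gy = np.meshgrid(x, yy)
        q = np.column_stack([gx.ravel(), gy.ravel()])
        _, idx = tree.query(q, k=k)
        summed = patches.areas[idx].sum(axis=1)
        values[r0:r0 + chunk] = (k / summed).reshape(len(yy), len(x)) * ARCMIN2_PER_DEG2
    return DensityMap(values=values, pixel_scale=mosaic.pixel_scale, k=k,
                      stride=stride, origin=(margin, margin))


def peak_cone_density(dmap: DensityMap) -> tuple[tuple[float, float], float, bool]:
    """Location (arcmin) and value of the density-map maximum (the PCD).

    Ties are broken by the first maximum in row-major order.  Returns
    ``((x, y), value, degenerate_tie)`` where ``degenerate_tie`` flags a map
    whose maximum is attained at more than one pixel.
    """
    vals = dmap.values
    flat = int(np.argmax(vals))
    r, c = np.unravel_index(flat, vals.shape)
    x, y = dmap.pixel_centers()
    vmax = vals[r, c]
    tie = int((vals == vmax).sum()) > 1
    return (float(x[c]), float(y[r])), float(vmax), tie


def cone_density_centroid(dmap: DensityMap, top_fraction: float = 0.20
                          ) -> tuple[float, float]:
    """Density-weighted centroid of the top-``top_fraction`` density pixels.

    Pixels with density at or above the (1 - top_fraction) quantile of the
    map are selected and their density-weighted mean position returned — the
    cone density centroid (CDC).
    """
    vals = dmap.values
    thresh = np.quantile(vals, 1.0 - top_fraction)
    mask = vals >= thresh
    x, y = dmap.pixel_centers()
    gx, gy = np.meshgrid(x, y)
    w = vals[mask]
    return (float(np.sum(gx[mask] * w) / w.sum()),
            float(np.sum(gy[mask] * w) / w.sum()))


def icd_from_density(density: float) -> float:
    """Average inter-cone distance (arcmin) for a hexagonal mosaic.

    ICD = sqrt(2 / (sqrt(3) * density)) with density in cones/deg^2, the
    spacing of a perfect hexagonal lattice with that density; returned in
    arcmin.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    return 60.0 * math.sqrt(2.0 / (math.sqrt(3.0) * density))


def nyquist_limit(icd: float, row_factor: float = HEX_ROW_FACTOR) -> float:
    """Nyquist sampling limit (arcmin) from the inter-cone distance.

    Based on the spacing between rows of a hexagonal lattice:
    N = (sqrt(3)/2) * ICD.  The conversion factor is configurable.
    """
    return row_factor * icd


@dataclass(frozen=True)
class FoveolarLandmarks:
    """Landmark set of a foveolar density map.

    PCD and CDC locations/values are derived from the map; the PRL (preferred
    retinal locus) is an externally supplied coordinate.  ICD and Nyquist are
    computed from the density at the CDC under the hexagonal-lattice
    assumption.  Positions in arcmin, densities in cones/deg^2.
    """

    pcd_location: tuple[float, float]
    pcd_value: float
    cdc_location: tuple[float, float]
    cdc_density: float
    icd_arcmin: float
    nyquist_arcmin: float
    prl_location: tuple[float, float] | None = None
    pcd_degenerate_tie: bool = False

    @property
    def nyquist_arcsec(self) -> float:
        return self.nyquist_arcmin * 60.0

    def location(self, name: str) -> tuple[float, float]:
        """Landmark coordinate by name: 'cdc', 'pcd', or 'prl'."""
        name = name.lower()
        if name == "cdc":
            return self.cdc_location
        if name == "pcd":
            return self.pcd_location
        if name == "prl":
            if self.prl_location is None:
                raise ValueError("PRL was not supplied for this mosaic")
            return self.prl_location
        raise KeyError(f"unknown landmark {name!r}")

    def to_dict(self) -> dict:
        return {
            "pcd": {"x_arcmin": self.pcd_location[0],
                    "y_arcmin": self.pcd_location[1],
                    "density_cones_per_deg2": self.pcd_value,
                    "degenerate_tie": self.pcd_degenerate_tie},
            "cdc": {"x_arcmin": self.cdc_location[0],
                    "y_arcmin": self.cdc_location[1],
                    "density_cones_per_deg2": self.cdc_density},
            "prl": (None if self.prl_location is None else
                    {"x_arcmin": self.prl_location[0],
                     "y_arcmin": self.prl_location[1]}),
            "icd_arcmin": self.icd_arcmin,
            "nyquist_arcmin": self.nyquist_arcmin,
            "nyquist_arcsec": self.nyquist_arcsec,
        }


def _map_value_at(dmap: DensityMap, location: tuple[float, float]) -> float:
    x, y = dmap.pixel_centers()
    c = int(np.clip(np.searchsorted(x, location[0]), 0, len(x) - 1))
    r = int(np.clip(np.searchsorted(y, location[1]), 0, len(y) - 1))
    return float(dmap.values[r, c])


def compute_landmarks(
    dmap: DensityMap,
    prl: tuple[float, float] | None = None,
    top_fraction: float = 0.20,
    row_factor: float = HEX_ROW_FACTOR,
) -> FoveolarLandmarks:
    """Derive the full landmark set (PCD, CDC, ICD, Nyquist) from a map."""
    pcd_loc, pcd_val, tie = peak_cone_density(dmap)
    cdc = cone_density_centroid(dmap, top_fraction=top_fraction)
    cdc_density = _map_value_at(dmap, cdc)
    icd = icd_from_density(cdc_density)
    return FoveolarLandmarks(
        pcd_location=pcd_loc,
        pcd_value=pcd_val,
        cdc_location=cdc,
        cdc_density=cdc_density,
        icd_arcmin=icd,
        nyquist_arcmin=nyquist_limit(icd, row_factor=row_factor),
        prl_location=prl,
        pcd_degenerate_tie=tie,
    )
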