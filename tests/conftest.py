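import numpy as np
import pytest

from foveolar import ConeMosaic, tessellate

HEX_SPACING = 0.54  # arcmin; corresponds to ~14,255 cones/deg^2


def hex_lattice(spacing: float = HEX_SPACING, n: int = 40):
    """Perfect hexagonal lattice mosaic.

    The image rectangle extends half a lattice period beyond the outermost
    cones, so boundary Voronoi cells clip to approximately their natural
    share and the lattice tiles the image at uniform density.
    """
    rows = []
    for b in range(n):
        for a in range(n):
            rows.append([(a + 0.5 * (b % 2)) * spacing,
                         b * np.sqrt(3.0) / 2.0 * spacing])
    pts = np.asarray(rows)
    border = np.array([spacing / 2.0, np.sqrt(3.0) / 4.0 * spacing])
    pts -= pts.min(axis=0) - border
    extent = (pts[:, 0].max() + border[0], pts[:, 1].max() + border[1])
    return ConeMosaic(cone_centers=pts, image_extent=extent, pixel_scale=0.1)


@pytest.fixture(scope="session")
def hex_mosaic():
    return hex_lattice()


@pytest.fixture(scope="session")
def hex_patches(hex_mosaic):
    return tessellate(hex_mosaic)


@pytest.fixture(scope="session")
def small_random_mosaic():
    """~250-cone jittered mosaic for brute-force comparisons."""
    rng = np.random.default_rng(42)
    pts = rng.uniform(0.5, 9.5, size=(250, 2))
    return ConeMosaic(cone_centers=pts, image_extent=(10.0, 10.0),
                      pixel_scale=0.1)


def straight_trace(n_frames=16, step=(0.5, 0.0), start=(10.0, 10.0),
                   dt_ms=100.0 / 3.0):
    from foveolar import GazeTrace
    t = np.arange(n_frames) * dt_ms
    xy = np.asarray(start) + np.outer(np.arange(n_frames), np.asarray(step))
    return GazeTrace(times_ms=t, xy=xy)
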