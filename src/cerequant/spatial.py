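"""Spatial statistics of cell distributions: per-layer density, the
nearest-neighbor spacing index, and Purkinje cell linear frequency.

The spacing index — (mean nearest-neighbor distance)^2 times density —
is dimensionless and scale-invariant: it equals 1 on a perfect square
grid, 0.25 for a homogeneous 2-D Poisson process (E[NN] = 1/(2*sqrt(λ))),
and falls below 0.25 for clustered patterns. No edge correction is
applied, a known (small) bias for small ROIs.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point

from .containers import LayerROI, SomaSet


def density(somas: SomaSet, roi: LayerROI) -> float:
    """Somas per um^2: count of centroids inside the ROI over its area.

    Membership uses the even-odd rule with boundary points counted as
    inside.
    """
    area = roi.area_um2
    if area <= 0:
        raise ValueError("ROI area must be positive")
    if len(somas) == 0:
        return 0.0
    inside = roi.contains_points(somas.xy())
    return float(inside.sum() / area)


def nearest_neighbor_distances(
    coords_xy: np.ndarray, pixel_size_um: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Distance from each soma to its nearest other soma, in um."""
    pts = np.atleast_2d(np.asarray(coords_xy, float))
    if pts.shape[0] < 2:
        raise ValueError("nearest-neighbor distances need at least 2 somas")
    sy, sx = pixel_size_um
    scaled = pts * np.array([sx, sy])
    tree = cKDTree(scaled)
    dists, _ = tree.query(scaled, k=2)
    return dists[:, 1]


def spacing_index(somas: SomaSet, roi: LayerROI) -> float:
    """(mean nearest-neighbor distance)^2 times density (dimensionless)."""
    if len(somas) < 2:
        raise ValueError("spacing index undefined for fewer than 2 somas")
    xy = somas.xy()
    inside = roi.contains_points(xy)
    pts = xy[inside]
    if pts.shape[0] < 2:
        raise ValueError("fewer than 2 somas inside the ROI")
    nn = nearest_neighbor_distances(pts, roi.pixel_size_um)
    dens = pts.shape[0] / roi.area_um2
    return float(nn.mean() ** 2 * dens)


def linear_frequency(
    somas: SomaSet,
    pcl_path: np.ndarray,
    pixel_size_um: tuple[float, float] = (1.0, 1.0),
    band_um: float = 15.0,
) -> float:
    """Purkinje somas per um of PCL path length.

    Somas are assigned to the PCL when their centroid lies within
    ``band_um`` of the polyline (about one soma diameter); the path
    length is the calibrated sum of segment lengths.
    """
    path = np.asarray(pcl_path, float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("PCL path needs at least 2 vertices")
    sy, sx = pixel_size_um
    scale = np.array([sx, sy])
    line = LineString(path * scale)
    if line.length <= 0:
        raise ValueError("zero-length PCL path")
    if len(somas) == 0:
        return 0.0
    pts = somas.xy() * scale
    n_on_path = sum(line.distance(Point(p)) <= band_um for p in pts)
    return float(n_on_path / line.length)


def section_average(values: list[float]) -> float:
    """Per-animal value: equal-weight mean of the per-section values."""
    if not values:
        raise ValueError("no section values to average")
    return float(np.mean(values))
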