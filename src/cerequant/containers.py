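"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Time-lapse data are 5-D arrays indexed ``(time, z, channel, y, x)``
  (TZCYX, matching the on-disk TIFF layout).
* Fixed-tissue sections are 4-D arrays indexed ``(z, channel, y, x)``.
* Voxel calibration is given in micrometers per pixel as ``(z, y, x)``.
* Channel 0 is the microglia (GFP) channel, channel 1 the Purkinje
  (tdTomato/Ai9) channel.
* Polygons and polylines are sequences of ``(x, y)`` vertices in pixel
  coordinates; areas/lengths are reported in calibrated units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

MICROGLIA = 0
PURKINJE = 1

CHANNEL_LABELS = ("microglia", "purkinje")


@dataclass
class TimelapseStack:
    """Two-channel in-vivo time-lapse z-stack.

    Attributes
    ----------
    data:
        Intensity array, shape ``(T, Z, C, Y, X)``, non-negative.
    voxel_size_um:
        Micrometers per pixel along ``(z, y, x)``.
    dt_min:
        Minutes between consecutive timepoints.
    channels:
        Channel labels, by convention ``("microglia", "purkinje")``.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dt_min: float = 5.0
    channels: tuple[str, ...] = CHANNEL_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"TimelapseStack expects a (T, Z, C, Y, X) array, got ndim={self.data.ndim}"
            )
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def channel(self, name_or_index: int | str) -> np.ndarray:
        """Return one channel as a ``(T, Z, Y, X)`` view."""
        idx = (
            name_or_index
            if isinstance(name_or_index, int)
            else self.channels.index(name_or_index)
        )
        return self.data[:, :, idx]

    def copy_with(self, data: np.ndarray) -> "TimelapseStack":
        return TimelapseStack(
            data=data,
            voxel_size_um=self.voxel_size_um,
            dt_min=self.dt_min,
            channels=self.channels,
        )


@dataclass
class SectionImage:
    """Single-timepoint two-channel confocal z-stack of a fixed section."""

    data: np.ndarray  # (Z, C, Y, X)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    channels: tuple[str, ...] = CHANNEL_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"SectionImage expects a (Z, C, Y, X) array, got ndim={self.data.ndim}"
            )

    def channel(self, name_or_index: int | str) -> np.ndarray:
        idx = (
            name_or_index
            if isinstance(name_or_index, int)
            else self.channels.index(name_or_index)
        )
        return self.data[:, idx]


@dataclass
class BinaryMask:
    """Thresholded object mask for one cell class (2-D or 3-D)."""

    data: np.ndarray
    pixel_size_um: tuple[float, ...] = (1.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim not in (2, 3):
            raise ValueError("BinaryMask must be 2-D or 3-D")

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class SomaSet:
    """Detected soma centroids with component sizes.

    Coordinates are ``(y, x)`` for 2-D and ``(z, y, x)`` for 3-D data,
    in pixel units.
    """

    coords: np.ndarray  # (n, 2) or (n, 3) float
    sizes: np.ndarray  # (n,) int component size in pixels

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 2)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def xy(self) -> np.ndarray:
        """Return planar (x, y) coordinates (drops z for 3-D sets)."""
        c = self.coords
        if c.shape[1] == 3:
            c = c[:, 1:]
        return c[:, ::-1]


@dataclass
class LayerROI:
    """Labeled layer region (ML+PCL, GL, WM) as a pixel-space polygon.

    ``holes`` lets an annular layer exclude the layers nested inside it.
    """

    label: str
    polygon: np.ndarray  # (n, 2) of (x, y) vertices
    pixel_size_um: tuple[float, float] = (1.0, 1.0)
    holes: list[np.ndarray] = field(default_factory=list)
    depth_um: float | None = None  # slab thickness, for volume-based metrics

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        shp = self.shapely
        if not shp.is_valid:
            raise ValueError(f"layer polygon for {self.label!r} is self-intersecting")

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon, [np.asarray(h, float) for h in self.holes])

    @property
    def area_um2(self) -> float:
        sy, sx = self.pixel_size_um
        # shoelace area in pixel^2 times the pixel footprint
        return float(self.shapely.area * sy * sx)

    @property
    def volume_um3(self) -> float:
        if self.depth_um is None:
            raise ValueError(f"layer {self.label!r} has no depth; volume undefined")
        return self.area_um2 * self.depth_um

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Even-odd membership test; boundary points count as inside."""
        shp = self.shapely
        return np.array(
            [shp.covers(Point(px, py)) for px, py in np.atleast_2d(xy)], dtype=bool
        )


def polyline_length_um(
    vertices: np.ndarray, pixel_size_um: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Calibrated length of an (x, y) polyline (sum of segment lengths)."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("polyline needs at least 2 vertices")
    sy, sx = pixel_size_um
    scaled = v * np.array([sx, sy])
    return float(LineString(scaled).length)


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of an (x, y) polygon in pixel^2."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
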