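"""Microglia process dynamics and injury-response quantification.

Implements the pixel-based motility index and surveillance ratio computed
between consecutive binarized timepoints, and the laser-ablation
convergence score (normalized front–core proximity).

Definitions, for consecutive binary masks A (earlier) and B (later):

* extended = |B \\ A|, retracted = |A \\ B|, stable = |A ∩ B|
* motility index (M.I.) = (extended + retracted) / stable
* surveillance ratio (S.R.) = |∪_t mask_t| / |mask_1|
* normalized proximity(t) = (A_front(t) − A_core) / (A_front(1) − A_core)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from skimage.measure import find_contours, label

from .containers import BinaryMask, polygon_area


@dataclass
class DynamicsResult:
    """Motility and surveillance for one mask sequence."""

    motility_per_pair: np.ndarray  # one value per consecutive transition
    motility_index: float  # mean over transitions
    motility_index_pooled: float  # pooled pixel counts over the whole hour
    surveillance_ratio: float
    layer: str = ""

    def __post_init__(self) -> None:
        if self.motility_index < 0 or self.surveillance_ratio < 1.0 - 1e-12:
            raise ValueError("M.I. must be >= 0 and S.R. >= 1")


@dataclass
class InjurySeries:
    """Front/core polygons and the normalized-proximity series."""

    core_polygon: np.ndarray  # (n, 2) of (x, y)
    front_polygons: list[np.ndarray] = field(default_factory=list)
    proximity: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _as_bool_stack(masks) -> np.ndarray:
    arrs = [m.data if isinstance(m, BinaryMask) else np.asarray(m, bool) for m in masks]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError("all masks must share the same shape")
    return np.stack(arrs)


def motility_index(masks, layer: str = "") -> DynamicsResult:
    """Motility index over an ordered sequence of 2-D binary masks.

    For each consecutive pair the sum of extended and retracted pixels is
    divided by stable pixels; the mean over transitions is reported as
    the M.I. (a pooled-pixel variant is also computed). Pairs with no
    stable pixels are excluded with a warning.
    """
    stack = _as_bool_stack(masks)
    if stack.shape[0] < 2:
        raise ValueError("motility index needs at least 2 timepoints")
    per_pair = []
    ext_tot = ret_tot = stab_tot = 0
    for a, b in zip(stack[:-1], stack[1:]):
        extended = int((b & ~a).sum())
        retracted = int((a & ~b).sum())
        stable = int((a & b).sum())
        ext_tot += extended
        ret_tot += retracted
        stab_tot += stable
        if stable == 0:
            warnings.warn("transition with zero stable pixels excluded from M.I.")
            continue
        per_pair.append((extended + retracted) / stable)
    per_pair = np.array(per_pair)
    mi = float(per_pair.mean()) if per_pair.size else float("nan")
    pooled = (ext_tot + ret_tot) / stab_tot if stab_tot else float("nan")
    return DynamicsResult(
        motility_per_pair=per_pair,
        motility_index=mi,
        motility_index_pooled=float(pooled),
        surveillance_ratio=surveillance_ratio(stack),
        layer=layer,
    )


def surveillance_ratio(masks) -> float:
    """Union of all timepoints' pixels over the first timepoint's pixels."""
    stack = _as_bool_stack(masks)
    if stack.shape[0] < 2:
        raise ValueError("surveillance ratio needs at least 2 timepoints")
    first = int(stack[0].sum())
    if first == 0:
        raise ValueError("first-timepoint mask is empty")
    return float(stack.any(axis=0).sum() / first)


def detect_front(
    mask: np.ndarray | BinaryMask, core_polygon: np.ndarray
) -> np.ndarray:
    """Trace the microglia front around an injury core.

    The front is the boundary polygon of the microglia-free connected
    region that contains the core centroid (the core's own pixels are
    treated as free space so an autofluorescent core does not split the
    region). With no microglia in the frame the front degenerates to the
    image rectangle.
    """
    m = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if m.ndim != 2:
        raise ValueError("front detection runs on a 2-D (max-projected) mask")
    ny, nx = m.shape
    core = np.asarray(core_polygon, float)
    cx, cy = core.mean(axis=0)
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("core centroid outside the field")
    if not m.any():
        warnings.warn("no microglia in frame; front set to the frame boundary")
        return np.array(
            [[0.0, 0.0], [nx - 1.0, 0.0], [nx - 1.0, ny - 1.0], [0.0, ny - 1.0]]
        )
    from skimage.draw import polygon2mask

    core_mask = polygon2mask((ny, nx), core[:, ::-1])
    free = (~m) | core_mask
    lab = label(free, connectivity=1)
    region_label = lab[int(round(cy)), int(round(cx))]
    if region_label == 0:  # centroid pixel itself is microglia
        region_label = lab[core_mask & (lab > 0)].min() if (core_mask & (lab > 0)).any() else 0
    region = lab == region_label
    contours = find_contours(region.astype(float), 0.5)
    if not contours:
        return core
    outer = max(contours, key=lambda c: abs(polygon_area(c[:, ::-1])))
    return outer[:, ::-1]  # (row, col) -> (x, y)


def injury_convergence(
    front_polygons: list[np.ndarray], core_polygon: np.ndarray
) -> InjurySeries:
    """Normalized front–core proximity series from polygon areas.

    Areas come from the shoelace formula. proximity(1) = 1 by
    construction; a front that has collapsed onto the core gives 0.
    """
    if len(front_polygons) < 2:
        raise ValueError("need at least 2 timepoints")
    a_core = polygon_area(np.asarray(core_polygon))
    areas = np.array([polygon_area(np.asarray(p)) for p in front_polygons])
    denom = areas[0] - a_core
    if denom <= 0:
        raise ValueError("first-timepoint front area equals the core area")
    proximity = np.clip((areas - a_core) / denom, 0.0, None)
    return InjurySeries(
        core_polygon=np.asarray(core_polygon),
        front_polygons=[np.asarray(p) for p in front_polygons],
        proximity=proximity,
    )


def front_area(polygon: np.ndarray) -> float:
    """Shoelace area of a front polygon (pixel^2)."""
    return polygon_area(np.asarray(polygon))


def polygon_to_shapely(polygon: np.ndarray) -> Polygon:
    return Polygon(np.asarray(polygon, float))
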