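"""Deterministic segmentation surrogates.

Replaces interactively trained pixel/object classifiers with fully
reproducible threshold + morphology operations: intensity binarization
with connected-component size exclusion, soma detection by morphological
opening, and microglia/Purkinje subcomponent classification. Connectivity
is fixed at 8 (2-D) / 26 (3-D).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops
from skimage.morphology import disk, skeletonize

from .containers import BinaryMask, SomaSet

DEFAULT_SOMA_RADIUS_PX = 3


def _full_connectivity(ndim: int) -> int:
    return ndim  # skimage: connectivity=ndim -> 8-conn (2-D) / 26-conn (3-D)


def binarize_objects(
    image: np.ndarray,
    threshold: float,
    min_size: int = 1,
    max_size: int | None = None,
    mask_label: str = "",
) -> BinaryMask:
    """Threshold an image and drop components outside a size window.

    Foreground is ``intensity >= threshold``; connected components with
    fewer than ``min_size`` or more than ``max_size`` pixels are removed.
    """
    if min_size < 1 or (max_size is not None and max_size < min_size):
        raise ValueError("need 0 < min_size <= max_size")
    image = np.asarray(image)
    fg = image >= threshold
    if fg.any() and (min_size > 1 or max_size is not None):
        lab = label(fg, connectivity=_full_connectivity(fg.ndim))
        sizes = np.bincount(lab.ravel())
        bad = np.zeros(len(sizes), dtype=bool)
        bad[1:] = sizes[1:] < min_size
        if max_size is not None:
            bad[1:] |= sizes[1:] > max_size
        fg &= ~bad[lab]
    return BinaryMask(data=fg, label=mask_label)


def detect_somas(
    mask_or_image: np.ndarray | BinaryMask,
    soma_min_size: int = 20,
    soma_max_size: int | None = None,
    opening_radius: int = DEFAULT_SOMA_RADIUS_PX,
    threshold: float | None = None,
) -> SomaSet:
    """Detect soma centroids as size-filtered components after opening.

    Morphological opening with a ball/disk of ``opening_radius`` removes
    thin processes so that only compact soma bodies remain; their
    centroids (pixel coordinates) and component sizes are returned.
    """
    if isinstance(mask_or_image, BinaryMask):
        mask = mask_or_image.data
    else:
        arr = np.asarray(mask_or_image)
        if arr.dtype == bool:
            mask = arr
        else:
            if threshold is None:
                raise ValueError("intensity input requires a threshold")
            mask = arr >= threshold
    if soma_min_size < 1 or (soma_max_size is not None and soma_max_size < soma_min_size):
        raise ValueError("invalid soma size bounds")
    opened = _opening(mask, opening_radius)
    lab = label(opened, connectivity=_full_connectivity(mask.ndim))
    coords, sizes = [], []
    for rp in regionprops(lab):
        if rp.area < soma_min_size:
            continue
        if soma_max_size is not None and rp.area > soma_max_size:
            continue
        coords.append(rp.centroid)
        sizes.append(rp.area)
    if not coords:
        return SomaSet(coords=np.zeros((0, mask.ndim)), sizes=np.zeros(0, dtype=int))
    return SomaSet(coords=np.array(coords), sizes=np.array(sizes))


def _opening(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius < 1:
        return mask.copy()
    if mask.ndim == 2:
        selem = disk(radius)
    else:
        # spherical structuring element for 3-D stacks
        r = radius
        zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        selem = zz**2 + yy**2 + xx**2 <= r**2
    return ndi.binary_opening(mask, structure=selem)


def classify_subcomponents(
    microglia_mask: BinaryMask | np.ndarray, r_soma: int = DEFAULT_SOMA_RADIUS_PX
) -> tuple[BinaryMask, BinaryMask]:
    """Partition a microglia mask into soma and process masks.

    Soma = morphological opening with radius ``r_soma`` (removing thin
    processes); process = everything else. The two masks form an exact
    partition of the input.
    """
    mask = microglia_mask.data if isinstance(microglia_mask, BinaryMask) else np.asarray(microglia_mask, bool)
    if not mask.any():
        raise ValueError("empty microglia mask")
    soma = _opening(mask, r_soma)
    if not soma.any():
        warnings.warn("opening removed everything; classifying all pixels as process")
    process = mask & ~soma
    return BinaryMask(soma, label="soma"), BinaryMask(process, label="process")


def classify_purkinje_components(
    purkinje_mask: BinaryMask | np.ndarray,
    layer: str,
    branch_dilation_radius: int = 2,
    soma_min_size: int = 20,
) -> dict[str, BinaryMask]:
    """Split a Purkinje mask into layer-appropriate subcomponents.

    In the ML the mask is skeletonized; branch points are skeleton pixels
    with three or more skeleton neighbors, dilated to a fixed radius, and
    dendrites are the remainder of the mask. In the PCL the only
    subcomponent is the soma (detected by opening + size filtering).
    """
    mask = purkinje_mask.data if isinstance(purkinje_mask, BinaryMask) else np.asarray(purkinje_mask, bool)
    if layer not in ("ML", "PCL"):
        raise ValueError("layer must be 'ML' or 'PCL'")
    if layer == "PCL":
        soma_mask = _opening(mask, DEFAULT_SOMA_RADIUS_PX)
        if soma_mask.any():
            lab = label(soma_mask, connectivity=_full_connectivity(soma_mask.ndim))
            sizes = np.bincount(lab.ravel())
            small = np.zeros(len(sizes), dtype=bool)
            small[1:] = sizes[1:] < soma_min_size
            soma_mask &= ~small[lab]
        return {"soma": BinaryMask(soma_mask, label="purkinje_soma")}
    if mask.ndim != 2:
        mask2d = mask.any(axis=0)
    else:
        mask2d = mask
    skel = skeletonize(mask2d)
    neighbors = ndi.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant") - skel
    branch_pts = skel & (neighbors >= 3)
    if branch_dilation_radius > 0 and branch_pts.any():
        branch_pts = ndi.binary_dilation(branch_pts, structure=disk(branch_dilation_radius))
    dendrites = mask2d & ~branch_pts
    return {
        "branch": BinaryMask(branch_pts & mask2d | branch_pts, label="purkinje_branch"),
        "dendrite": BinaryMask(dendrites, label="purkinje_dendrite"),
    }


def count_branch_points(purkinje_mask: np.ndarray) -> int:
    """Number of distinct branch-point clusters in a 2-D mask skeleton."""
    skel = skeletonize(np.asarray(purkinje_mask, bool))
    neighbors = ndi.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant") - skel
    branch_pts = skel & (neighbors >= 3)
    lab = label(branch_pts, connectivity=2)
    return int(lab.max())
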