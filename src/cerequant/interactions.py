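"""Microglia–Purkinje cell interaction metrics.

Volume fractions (voxels per region volume), 3-D binary-mask overlap
(voxelwise AND of the two binarized channels), normalized interaction
(overlap voxels per microglia voxel, averaged over timepoints or
sections), and the two time-resolved indices computed on max-projected
interaction masks: the dynamic interaction index (the motility-index
formula applied to interaction masks) and the coverage index (union of
interaction pixels over all timepoints, per frame pixel).

The granule layer is excluded from interaction analysis because Purkinje
cell axons are too sparse there for overlap to be meaningful.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import BinaryMask
from .dynamics import DynamicsResult, motility_index

INTERACTION_LAYERS = ("ML", "PCL", "WM")  # GL excluded


def _data(mask) -> np.ndarray:
    return mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)


def volume_fraction(mask, region_voxels: int | np.ndarray) -> float:
    """Mask voxels per region voxel: |mask ∩ region| / |region|."""
    m = _data(mask)
    if isinstance(region_voxels, np.ndarray):
        region = np.asarray(region_voxels, bool)
        n_region = int(region.sum())
        n_mask = int((m & region).sum())
    else:
        n_region = int(region_voxels)
        n_mask = int(m.sum())
    if n_region <= 0:
        raise ValueError("region volume must be positive")
    return n_mask / n_region


def interaction_overlap(microglia, purkinje) -> tuple[BinaryMask, int]:
    """Voxelwise AND of the binarized microglia and Purkinje masks."""
    m, p = _data(microglia), _data(purkinje)
    if m.shape != p.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {p.shape}")
    overlap = m & p
    return BinaryMask(overlap, label="interaction"), int(overlap.sum())


def normalized_interaction(
    overlap_counts: np.ndarray, microglia_counts: np.ndarray
) -> float:
    """Mean over timepoints/sections of overlap voxels per microglia voxel.

    Entries with an empty microglia mask are excluded with a warning
    rather than zero-filled.
    """
    ov = np.asarray(overlap_counts, float)
    mg = np.asarray(microglia_counts, float)
    if ov.shape != mg.shape:
        raise ValueError("overlap and microglia count arrays must align")
    keep = mg > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} timepoint(s) with empty microglia mask excluded")
    if not keep.any():
        raise ValueError("no timepoints with nonempty microglia mask")
    return float((ov[keep] / mg[keep]).mean())


def normalized_interaction_from_masks(
    microglia_masks, purkinje_masks
) -> float:
    """Normalized interaction computed directly from per-timepoint 3-D masks."""
    ov, mg = [], []
    for m, p in zip(microglia_masks, purkinje_masks):
        _, count = interaction_overlap(m, p)
        ov.append(count)
        mg.append(int(_data(m).sum()))
    return normalized_interaction(np.array(ov), np.array(mg))


def dynamic_interaction_index(interaction_masks) -> DynamicsResult:
    """Motility-index formula applied to max-projected interaction masks."""
    masks = [_data(m) for m in interaction_masks]
    masks = [m.any(axis=0) if m.ndim == 3 else m for m in masks]
    return motility_index(masks, layer="interaction")


def coverage_index(interaction_masks) -> float:
    """Union of interaction pixels over all timepoints per frame pixel."""
    masks = [_data(m) for m in interaction_masks]
    if not masks:
        raise ValueError("need at least 1 timepoint")
    masks = [m.any(axis=0) if m.ndim == 3 else m for m in masks]
    union = np.stack(masks).any(axis=0)
    return float(union.sum() / union.size)
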