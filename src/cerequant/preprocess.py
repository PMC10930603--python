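"""Time-lapse preprocessing: blinding, drift correction, bleed-through
subtraction, background correction, temporal PCA denoising, and layer
substack creation.

All operations preserve array shape and calibration metadata. Drift is
estimated at integer-pixel resolution by cross-correlating the microglia
channel's max projections against the first timepoint; bleed-through is a
single scalar fraction (alpha) of the Purkinje channel present in the
microglia channel, estimated by least squares over a Purkinje-only mask.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation

from .containers import MICROGLIA, PURKINJE, TimelapseStack
from .synthgen import _shift2d


@dataclass
class DriftModel:
    """Per-timepoint integer (dy, dx) translations relative to timepoint 1."""

    offsets: np.ndarray  # (T, 2) int

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=int)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise ValueError("offsets must be (T, 2)")
        if tuple(self.offsets[0]) != (0, 0):
            raise ValueError("offset at timepoint 1 must be (0, 0)")


@dataclass
class BleedModel:
    """Bleed fraction of the Purkinje channel present in the microglia channel."""

    alpha: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def blind_dataset(
    paths: list[str], seed: int
) -> tuple[dict[str, str], pd.DataFrame]:
    """Assign opaque blinded ids to a set of stack paths.

    Returns a ``{path: blinded_id}`` map plus a key table that round-trips
    the original names. The permutation is a seeded bijection so the same
    seed always produces the same blinding.
    """
    if len(paths) == 0:
        raise ValueError("need at least one stack to blind")
    if len(set(paths)) != len(paths):
        raise ValueError("duplicate paths in blinding input")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(paths))
    mapping = {}
    for rank, idx in enumerate(perm):
        digest = hashlib.sha1(f"{seed}:{rank}".encode()).hexdigest()[:8]
        mapping[paths[idx]] = f"blind_{digest}"
    key = pd.DataFrame(
        {"blinded_id": list(mapping.values()), "original_path": list(mapping.keys())}
    )
    return mapping, key


def correct_drift(stack: TimelapseStack) -> tuple[TimelapseStack, DriftModel]:
    """Register every timepoint to timepoint 1 by integer translation.

    The shift is estimated by phase cross-correlation of the microglia
    channel's z max projections and applied to both channels with
    zero-padded edges.
    """
    if stack.n_timepoints < 2:
        raise ValueError("drift correction needs at least 2 timepoints")
    mic = stack.channel(MICROGLIA)
    ref = mic[0].max(axis=0)
    offsets = np.zeros((stack.n_timepoints, 2), dtype=int)
    out = stack.data.copy()
    for t in range(1, stack.n_timepoints):
        moving = mic[t].max(axis=0)
        if not moving.any():
            warnings.warn(f"timepoint {t} is all-zero; assuming zero drift")
            continue
        shift, _, _ = phase_cross_correlation(ref, moving, upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        offsets[t] = (-dy, -dx)  # estimated drift of the frame
        out[t] = _shift2d(out[t], np.array([dy, dx]))
    return stack.copy_with(out), DriftModel(offsets)


def estimate_bleedthrough(
    stack: TimelapseStack, purkinje_only_mask: np.ndarray
) -> BleedModel:
    """Estimate the bleed fraction alpha over a Purkinje-only mask.

    alpha is the least-squares through-origin slope of microglia-channel
    intensity on Purkinje-channel intensity across the masked voxels,
    after per-frame modal-background subtraction of both channels. The
    slope is invariant to uniform brightness rescaling of the Purkinje
    channel, and forcing the line through the origin keeps it
    identifiable even when the masked Purkinje signal is nearly uniform.
    """
    mask = np.asarray(purkinje_only_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty Purkinje-only mask")
    mic = stack.channel(MICROGLIA).astype(float)
    purk = stack.channel(PURKINJE).astype(float)
    mic = mic - np.array([_frame_mode(f) for f in mic])[:, None, None, None]
    purk = purk - np.array([_frame_mode(f) for f in purk])[:, None, None, None]
    if mask.shape == mic.shape[1:]:  # single-timepoint (Z, Y, X) mask
        mask = np.broadcast_to(mask, mic.shape)
    x = purk[mask]
    y = mic[mask]
    denom = float((x * x).sum())
    if denom <= 0:
        raise ValueError("Purkinje-only mask carries no signal")
    slope = float((x * y).sum() / denom)
    return BleedModel(alpha=max(slope, 0.0))


def _frame_mode(frame: np.ndarray) -> float:
    """Most frequent intensity of a frame (background estimate)."""
    vals = np.round(frame).astype(np.int64).ravel()
    counts = np.bincount(vals - vals.min())
    return float(counts.argmax() + vals.min())


def subtract_bleedthrough(
    stack: TimelapseStack, bleed: BleedModel
) -> TimelapseStack:
    """Background-correct both channels, then remove bleed-through.

    Per timepoint, the modal intensity of each channel is subtracted as
    background; the brightness-compensated Purkinje channel (alpha times
    its intensity) is then subtracted from the microglia channel. The
    result is clipped at zero.
    """
    out = stack.data.astype(np.float64).copy()
    for t in range(stack.n_timepoints):
        for c in range(out.shape[2]):
            out[t, :, c] -= _frame_mode(out[t, :, c])
    out[:, :, MICROGLIA] -= bleed.alpha * out[:, :, PURKINJE]
    np.clip(out, 0, None, out=out)
    return stack.copy_with(out)


def pca_denoise(stack: TimelapseStack, k: int) -> TimelapseStack:
    """Temporal low-rank denoising: keep the top-k principal components.

    Each channel is unfolded to a (timepoints x pixels) matrix, mean-
    centered over time, and reconstructed from its leading k principal
    components. With k equal to the number of timepoints this is the
    identity within float tolerance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    nt = stack.n_timepoints
    out = np.empty_like(stack.data, dtype=np.float64)
    for c in range(stack.data.shape[2]):
        x = stack.data[:, :, c].reshape(nt, -1).astype(np.float64)
        mean = x.mean(axis=0, keepdims=True)
        xc = x - mean
        rank = min(nt, xc.shape[1])
        if k >= rank:
            if k > rank:
                warnings.warn("k exceeds rank; returning identity reconstruction")
            recon = x
        else:
            u, s, vt = np.linalg.svd(xc, full_matrices=False)
            recon = (u[:, :k] * s[:k]) @ vt[:k] + mean
        out[:, :, c] = recon.reshape(stack.data[:, :, c].shape)
    np.clip(out, 0, None, out=out)  # low-rank reconstruction can dip below 0
    return stack.copy_with(out)


def split_layers(
    stack: TimelapseStack, pcl_start_z: int, n_slices: int
) -> tuple[TimelapseStack, TimelapseStack]:
    """Cut equal-depth ML and PCL substacks around the layer boundary.

    The ML substack is the ``n_slices`` z planes ending at ``pcl_start_z``
    (exclusive); the PCL substack the ``n_slices`` planes starting there
    (inclusive). Both intervals are half-open.
    """
    depth = stack.n_slices
    if pcl_start_z + n_slices > depth or pcl_start_z < n_slices:
        raise ValueError(
            f"layer split out of range: pcl_start_z={pcl_start_z}, "
            f"n_slices={n_slices}, depth={depth}"
        )
    ml = stack.copy_with(stack.data[:, pcl_start_z - n_slices : pcl_start_z])
    pcl = stack.copy_with(stack.data[:, pcl_start_z : pcl_start_z + n_slices])
    return ml, pcl


def max_project(data: np.ndarray | TimelapseStack, z_axis: int = 1) -> np.ndarray:
    """Per-pixel maximum over z.

    For a :class:`TimelapseStack` this returns a (T, C, Y, X) array; for a
    bare array the given axis is reduced.
    """
    if isinstance(data, TimelapseStack):
        return data.data.max(axis=1)
    return np.asarray(data).max(axis=z_axis)
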