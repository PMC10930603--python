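"""Reading and writing of stacks, masks, ROIs, and result tables.

Time-lapse stacks are stored as multi-page TIFF in TZCYX order with a
JSON sidecar carrying calibration and any ground truth; layer ROIs and
polylines are JSON lists of (x, y) pixel coordinates; soma sets and
metric tables are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import BinaryMask, SectionImage, SomaSet, TimelapseStack


def write_stack(stack: TimelapseStack, path: str | Path, sidecar: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32), metadata={"axes": "TZCYX"})
    meta = {
        "axes": "TZCYX",
        "voxel_size_um": list(stack.voxel_size_um),
        "dt_min": stack.dt_min,
        "channels": list(stack.channels),
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=_jsonable))


def read_stack(path: str | Path) -> TimelapseStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TimelapseStack(
        data=data,
        voxel_size_um=tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0))),
        dt_min=float(meta.get("dt_min", 5.0)),
        channels=tuple(meta.get("channels", ("microglia", "purkinje"))),
    )


def write_section(section: SectionImage, path: str | Path, sidecar: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, section.data.astype(np.float32), metadata={"axes": "ZCYX"})
    meta = {"axes": "ZCYX", "voxel_size_um": list(section.voxel_size_um)}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=_jsonable))


def read_section(path: str | Path) -> SectionImage:
    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SectionImage(
        data=data, voxel_size_um=tuple(meta.get("voxel_size_um", (1.0, 1.0, 1.0)))
    )


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    tifffile.imwrite(
        Path(path), mask.data.astype(np.uint8) * 255, photometric="minisblack"
    )


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    return BinaryMask(tifffile.imread(Path(path)) > 0, label=label)


def write_somas(somas: SomaSet, path: str | Path) -> None:
    ndim = somas.coords.shape[1]
    cols = ["y", "x"] if ndim == 2 else ["z", "y", "x"]
    df = pd.DataFrame(somas.coords, columns=cols)
    df.insert(0, "id", np.arange(len(somas)))
    df["size"] = somas.sizes
    df.to_csv(Path(path), index=False)


def read_somas(path: str | Path) -> SomaSet:
    df = pd.read_csv(Path(path))
    cols = [c for c in ("z", "y", "x") if c in df.columns]
    return SomaSet(coords=df[cols].to_numpy(float), sizes=df["size"].to_numpy(int))


def write_polygons(polygons: dict[str, np.ndarray], path: str | Path) -> None:
    """Write named (x, y) polygons/polylines as JSON."""
    payload = {k: np.asarray(v, float).tolist() for k, v in polygons.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_polygons(path: str | Path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    return {k: np.asarray(v, float) for k, v in payload.items()}


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
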