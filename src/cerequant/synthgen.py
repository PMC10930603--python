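"""Synthetic two-photon / confocal image generator with known ground truth.

Emulates the imaging conditions of the cerebellar microglia–Purkinje cell
experiments this package quantifies: GFP-labeled branched microglia with
motile processes, tdTomato Purkinje dendrites (molecular layer) and somas
(Purkinje cell layer), channel bleed-through, stage drift, layered lobule
geometry, laser-ablation injury convergence, and configurable multiplicative
group effects. Every generated dataset carries its full ground truth so the
downstream measurement stages can be validated without external data.

Geometry conventions
--------------------
In-vivo stacks are (T, Z, C, Y, X) with the molecular layer (ML) at low z
indices and the Purkinje cell layer (PCL) below it (higher z), matching an
imaging axis that descends from the pial surface. Fixed sections are
(Z, C, Y, X) with the cerebellar layers laid out as curved bands in the
(y, x) plane: ML+PCL on top, granule layer (GL) in the middle, white matter
(WM) at the bottom.

The process-dynamics model is deliberately simple: per 5-min interval a
controlled number of process tip pixels is retracted and the same number
extended elsewhere, so that the expected motility index equals the
configured ``process_turnover`` exactly. Real microglia are not modeled
generatively by the source experiments (they are measured), so this model
exists to make motility/surveillance ground truth analytically controllable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .containers import (
    MICROGLIA,
    PURKINJE,
    LayerROI,
    SectionImage,
    TimelapseStack,
    polyline_length_um,
)

# emission amplitude of a labeled voxel before bleed-through and noise
AMPLITUDE = 1000.0

@dataclass
class SynthConfig:
    """Generator configuration.

    Defaults mirror the acquisition geometry of the source experiments
    (101 one-micron z-steps, 12 timepoints at 5-min intervals) with a
    field of view scaled for desk-size runs.
    """

    image_shape: tuple[int, int] = (160, 160)  # (Y, X) pixels
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x)
    n_timepoints: int = 12
    dt_min: float = 5.0
    zstack_depth_um: float = 101.0
    # somas per um^2 of projected layer area (in vivo) or ROI area (fixed)
    microglia_density_per_layer: dict[str, float] = field(
        default_factory=lambda: {
            "ML": 1.5e-4,
            "PCL": 1.5e-4,
            "ML+PCL": 1.5e-4,
            "GL": 1.5e-4,
            "WM": 2.0e-4,
        }
    )
    # fraction of pixels extended+retracted per interval; float or per-layer dict
    process_turnover: float | dict[str, float] = 0.05
    bleed_alpha: float = 0.1
    drift_px: int = 0  # max per-timepoint random-walk step, 0 disables
    noise_sd: float = 10.0
    pcl_soma_spacing_um: float = 30.0
    # multiplicative effects keyed "treatment" or "treatment:sex" mapping
    # generator parameter names to multipliers
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    treatment: str = "saline"
    sex: str = "M"
    placement: str = "grid"  # "grid" (perturbed) or "poisson"
    seed: int = 0

    # morphology knobs (defaults chosen for testability, not realism)
    soma_radius_um: float = 3.5
    purkinje_soma_radius_um: float = 7.0
    n_processes: int = 4
    process_length_um: float = 25.0
    pcl_start_frac: float = 0.65  # fraction of stack depth where the PCL begins
    fixed_n_slices: int = 25
    microglia_arbors: bool = True

    # injury-series knobs
    injury_core_radius_px: float = 10.0
    injury_front_radius_px: float = 40.0
    injury_rate_px: float = 2.0  # inward front speed, px per interval

    def __post_init__(self) -> None:
        y, x = self.image_shape
        if y < 16 or x < 16:
            raise ValueError("degenerate image_shape: every axis must be >= 16 px")
        if not (0.0 <= self.bleed_alpha < 1.0):
            raise ValueError("bleed_alpha must be in [0, 1)")
        turnovers = (
            self.process_turnover.values()
            if isinstance(self.process_turnover, dict)
            else [self.process_turnover]
        )
        for m in turnovers:
            if not (0.0 <= m <= 1.0):
                raise ValueError("process_turnover must be in [0, 1]")
        if any(d < 0 for d in self.microglia_density_per_layer.values()):
            raise ValueError("densities must be >= 0")
        if self.noise_sd < 0 or self.pcl_soma_spacing_um <= 0:
            raise ValueError("noise_sd must be >= 0 and soma spacing > 0")
        if self.placement not in ("grid", "poisson"):
            raise ValueError("placement must be 'grid' or 'poisson'")

    @property
    def n_z(self) -> int:
        return int(round(self.zstack_depth_um / self.voxel_size_um[0]))

    def effect(self, param: str) -> float:
        """Resolve the multiplicative group effect on a generator parameter."""
        mult = 1.0
        for key in (self.treatment, f"{self.treatment}:{self.sex}", f"*:{self.sex}"):
            mult *= self.group_effects.get(key, {}).get(param, 1.0)
        return mult

    def turnover_for(self, layer: str) -> float:
        base = (
            self.process_turnover.get(layer, 0.0)
            if isinstance(self.process_turnover, dict)
            else self.process_turnover
        )
        return base * self.effect("process_turnover")

    def replace(self, **kwargs: Any) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Pre-noise, pre-drift ground truth emitted alongside synthetic images."""

    microglia_masks: np.ndarray | None = None  # (T, Z, Y, X) bool
    purkinje_mask: np.ndarray | None = None  # (Z, Y, X) bool
    layer_z: dict[str, tuple[int, int]] = field(default_factory=dict)
    drift_offsets: np.ndarray | None = None  # (T, 2) int (dy, dx)
    cells: list[dict[str, Any]] = field(default_factory=list)
    # fixed-section fields
    microglia_somas: dict[str, np.ndarray] = field(default_factory=dict)
    purkinje_somas: np.ndarray | None = None  # (n, 2) of (y, x)
    pcl_path: np.ndarray | None = None  # (n, 2) of (x, y)
    layer_masks: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)

    def layer_projection(self, layer: str, t: int) -> np.ndarray:
        """Max-projected ground-truth microglia mask for one layer/timepoint."""
        z0, z1 = self.layer_z[layer]
        return self.microglia_masks[t, z0:z1].any(axis=0)


# --------------------------------------------------------------------------
# microglia morphology and dynamics
# --------------------------------------------------------------------------


def _sphere_coords(
    center: tuple[float, float, float],
    radius: float,
    shape: tuple[int, int, int],
    z_range: tuple[int, int] | None = None,
) -> np.ndarray:
    cz, cy, cx = center
    r = int(np.ceil(radius))
    zz, yy, xx = np.mgrid[
        max(0, int(cz) - r) : min(shape[0], int(cz) + r + 1),
        max(0, int(cy) - r) : min(shape[1], int(cy) + r + 1),
        max(0, int(cx) - r) : min(shape[2], int(cx) + r + 1),
    ]
    keep = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    coords = np.stack([zz[keep], yy[keep], xx[keep]], axis=1)
    if z_range is not None:
        coords = coords[(coords[:, 0] >= z_range[0]) & (coords[:, 0] < z_range[1])]
    return coords


class _Microglia:
    """One branched microglia: a static soma plus motile process branches.

    Branch voxels occupy (y, x) positions unique within the cell so the
    z max-projection is injective and pixel turnover in 3-D translates
    one-to-one into projected-pixel turnover.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        soma_center: tuple[int, int, int],
        cfg: SynthConfig,
        z_range: tuple[int, int],
        layer: str,
    ) -> None:
        self.layer = layer
        self.z_range = z_range
        shape = (cfg.n_z, *cfg.image_shape)
        self.shape = shape
        self.soma_center = soma_center
        r_soma = cfg.soma_radius_um / cfg.voxel_size_um[1]
        self.soma = _sphere_coords(soma_center, r_soma, shape, z_range)
        self.occupied: set[tuple[int, int]] = {
            (int(y), int(x)) for _, y, x in self.soma
        }
        self.branches: list[list[tuple[int, int, int]]] = []
        length_px = cfg.process_length_um / cfg.voxel_size_um[1]
        for _ in range(cfg.n_processes):
            theta = rng.uniform(0, 2 * np.pi)
            direction = np.array([np.sin(theta), np.cos(theta)])
            branch: list[tuple[int, int, int]] = []
            pos = np.array(soma_center[1:], dtype=float) + direction * (r_soma + 1)
            z = soma_center[0]
            target = int(rng.uniform(0.6, 1.4) * length_px)
            for _ in range(target):
                step = self._step(rng, direction)
                pos = pos + step
                direction = 0.7 * direction + 0.3 * step
                direction /= np.linalg.norm(direction) + 1e-9
                if rng.random() < 0.15:
                    z = int(np.clip(z + rng.integers(-1, 2), z_range[0], z_range[1] - 1))
                py, px = int(round(pos[0])), int(round(pos[1]))
                if not (0 <= py < shape[1] and 0 <= px < shape[2]):
                    break
                if (py, px) in self.occupied:
                    continue
                branch.append((z, py, px))
                self.occupied.add((py, px))
            if branch:
                self.branches.append(branch)

    @staticmethod
    def _step(rng: np.random.Generator, direction: np.ndarray) -> np.ndarray:
        jitter = rng.normal(scale=0.6, size=2)
        step = direction + jitter
        step = step / (np.abs(step).max() + 1e-9)
        return np.round(step)

    @property
    def n_pixels(self) -> int:
        return len(self.soma) + sum(len(b) for b in self.branches)

    def turnover_step(self, rng: np.random.Generator, m: float) -> None:
        """Retract and extend process tips for one interval.

        The retraction count r solves (2r) / (N - r) = m so that the
        expected motility index of the transition equals m.
        """
        if m <= 0:
            return
        # motility is measured on z max projections, so the turnover count
        # is controlled against the projected (y, x) footprint of the cell
        n_total = len(self.occupied)
        r = int(round(m * n_total / (2.0 + m)))
        removed = 0
        just_removed: set[tuple[int, int]] = set()
        live = [b for b in self.branches if len(b) > 2]
        while removed < r and live:
            b = live[rng.integers(len(live))]
            z, y, x = b.pop()
            self.occupied.discard((y, x))
            just_removed.add((y, x))
            removed += 1
            live = [b for b in self.branches if len(b) > 2]
        added = 0
        attempts = 0
        while added < removed and attempts < 50 * max(removed, 1):
            attempts += 1
            if not self.branches:
                break
            b = self.branches[rng.integers(len(self.branches))]
            tail = b[-1]
            if len(b) >= 2:
                prev = b[-2]
                direction = np.array([tail[1] - prev[1], tail[2] - prev[2]], float)
            else:
                direction = np.array(
                    [tail[1] - self.soma_center[1], tail[2] - self.soma_center[2]],
                    float,
                )
            direction /= np.linalg.norm(direction) + 1e-9
            step = self._step(rng, direction)
            py, px = int(tail[1] + step[0]), int(tail[2] + step[1])
            z = int(
                np.clip(
                    tail[0] + (rng.integers(-1, 2) if rng.random() < 0.15 else 0),
                    self.z_range[0],
                    self.z_range[1] - 1,
                )
            )
            if not (0 <= py < self.shape[1] and 0 <= px < self.shape[2]):
                continue
            # a pixel retracted this same interval must not be re-entered,
            # or the transition would register neither change
            if (py, px) in self.occupied or (py, px) in just_removed:
                continue
            b.append((z, py, px))
            self.occupied.add((py, px))
            added += 1

    def voxels(self) -> np.ndarray:
        parts = [self.soma] + [np.array(b) for b in self.branches if b]
        return np.concatenate(parts, axis=0)


def _place_somas_2d(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[int, int, int, int],
    placement: str,
) -> np.ndarray:
    """Place n soma centers in (y0, y1, x0, x1), perturbed grid or Poisson."""
    y0, y1, x0, x1 = bounds
    if n <= 0:
        return np.zeros((0, 2))
    if placement == "poisson":
        ys = rng.uniform(y0, y1, size=n)
        xs = rng.uniform(x0, x1, size=n)
        return np.stack([ys, xs], axis=1)
    # perturbed grid: near-square lattice covering the bounds
    aspect = (x1 - x0) / max(y1 - y0, 1)
    ny = max(1, int(round(np.sqrt(n / aspect))))
    nx = max(1, int(np.ceil(n / ny)))
    sy, sx = (y1 - y0) / ny, (x1 - x0) / nx
    pts = []
    for i in range(ny):
        for j in range(nx):
            cy = y0 + (i + 0.5) * sy + rng.uniform(-0.2, 0.2) * sy
            cx = x0 + (j + 0.5) * sx + rng.uniform(-0.2, 0.2) * sx
            pts.append((cy, cx))
    pts = np.array(pts)
    return pts[rng.permutation(len(pts))[:n]]


# --------------------------------------------------------------------------
# in-vivo time-lapse
# --------------------------------------------------------------------------


def generate_timelapse(config: SynthConfig) -> tuple[TimelapseStack, GroundTruth]:
    """Generate a two-channel in-vivo time-lapse with motile microglia.

    The microglia channel holds branched cells whose process tips extend
    and retract at ``process_turnover`` per 5-min interval; the Purkinje
    channel holds static quasi-planar dendritic arbors in the ML and a
    soma monolayer at the ML/PCL boundary. Bleed-through, drift, and
    additive noise are applied in that order; the returned ground truth
    is pre-noise and pre-drift.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    nz, nt = config.n_z, config.n_timepoints
    vz, vy, vx = config.voxel_size_um

    pcl_start = int(round(config.pcl_start_frac * nz))
    layer_z = {"ML": (0, pcl_start), "PCL": (pcl_start, nz)}

    # --- microglia ---------------------------------------------------------
    area_um2 = ny * vy * nx * vx
    cells: list[_Microglia] = []
    margin = int(config.soma_radius_um + 2)
    for layer, (z0, z1) in layer_z.items():
        dens = config.microglia_density_per_layer.get(layer, 0.0)
        dens *= config.effect("microglia_density")
        n = max(1, int(round(dens * area_um2))) if dens > 0 else 0
        centers = _place_somas_2d(
            rng, n, (margin, ny - margin, margin, nx - margin), config.placement
        )
        for cy, cx in centers:
            pad = min(4, max((z1 - z0) // 3, 0))
            cz = int(np.clip(rng.uniform(z0 + pad, z1 - pad), z0, z1 - 1))
            cells.append(
                _Microglia(rng, (cz, int(cy), int(cx)), config, (z0, z1), layer)
            )

    mic_masks = np.zeros((nt, nz, ny, nx), dtype=bool)
    for t in range(nt):
        if t > 0:
            for cell in cells:
                cell.turnover_step(rng, config.turnover_for(cell.layer))
        for cell in cells:
            v = cell.voxels()
            mic_masks[t, v[:, 0], v[:, 1], v[:, 2]] = True

    # --- Purkinje cells ----------------------------------------------------
    purk = np.zeros((nz, ny, nx), dtype=bool)
    spacing_px = config.pcl_soma_spacing_um / vx
    spacing_px /= config.effect("pcl_linear_density")
    r_ps = config.purkinje_soma_radius_um / vy
    soma_z = min(nz - 1, pcl_start + int(r_ps))
    n_rows = max(1, int(ny / spacing_px))
    soma_centers = []
    for i in range(n_rows):
        for j in range(max(1, int(nx / spacing_px))):
            cy = (i + 0.5) * spacing_px + rng.uniform(-2, 2)
            cx = (j + 0.5) * spacing_px + rng.uniform(-2, 2)
            if 0 <= cy < ny and 0 <= cx < nx:
                soma_centers.append((soma_z, cy, cx))
    for c in soma_centers:
        v = _sphere_coords(c, r_ps, (nz, ny, nx))
        purk[v[:, 0], v[:, 1], v[:, 2]] = True
        _grow_purkinje_arbor(rng, purk, c, pcl_start)

    # --- emit image --------------------------------------------------------
    img = np.zeros((nt, nz, 2, ny, nx), dtype=np.float32)
    img[:, :, PURKINJE] = AMPLITUDE * purk[None]
    img[:, :, MICROGLIA] = AMPLITUDE * mic_masks
    img[:, :, MICROGLIA] += config.bleed_alpha * img[:, :, PURKINJE]

    offsets = np.zeros((nt, 2), dtype=int)
    if config.drift_px > 0:
        steps = rng.integers(-config.drift_px, config.drift_px + 1, size=(nt - 1, 2))
        offsets[1:] = np.cumsum(steps, axis=0)
        for t in range(1, nt):
            img[t] = _shift2d(img[t], offsets[t])
    if config.noise_sd > 0:
        img += rng.normal(scale=config.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0, None, out=img)

    stack = TimelapseStack(
        data=img, voxel_size_um=config.voxel_size_um, dt_min=config.dt_min
    )
    truth = GroundTruth(
        microglia_masks=mic_masks,
        purkinje_mask=purk,
        layer_z=layer_z,
        drift_offsets=offsets,
        cells=[
            {
                "layer": c.layer,
                "soma_center": c.soma_center,
                "n_branches": len(c.branches),
            }
            for c in cells
        ],
        params={
            "turnover": {lay: config.turnover_for(lay) for lay in layer_z},
            "bleed_alpha": config.bleed_alpha,
            "n_purkinje_somas": len(soma_centers),
        },
    )
    return stack, truth


def _grow_purkinje_arbor(
    rng: np.random.Generator,
    volume: np.ndarray,
    soma_center: tuple[int, float, float],
    pcl_start: int,
) -> None:
    """Quasi-planar bifurcating dendritic arbor ascending through the ML.

    Segments climb toward z=0 (the pial surface) fanning out in y while
    staying near the soma's x plane; each generation bifurcates until a
    fixed depth, writing voxels directly into ``volume``.
    """
    nz, ny, nx = volume.shape
    _, cy, cx = soma_center
    stack = [(float(pcl_start - 1), float(cy), float(cx), 0.0, 0)]
    while stack:
        z, y, x, lateral, depth = stack.pop()
        seg = int(rng.uniform(8, 16))
        alive = True
        for _ in range(seg):
            z -= 1.0
            y += lateral + rng.normal(scale=0.3)
            x += rng.normal(scale=0.2)  # quasi-planar: little spread in x
            iz, iy, ix = int(round(z)), int(round(y)), int(round(x))
            if iz < 0 or not (0 <= iy < ny and 0 <= ix < nx):
                alive = False
                break
            volume[iz, iy, ix] = True
        if not alive or z <= 1 or depth >= 3:
            continue
        spread = rng.uniform(0.4, 0.9)
        stack.append((z, y, x, lateral + spread, depth + 1))
        stack.append((z, y, x, lateral - spread, depth + 1))


def _shift2d(frame: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Integer (dy, dx) translation of the trailing (y, x) axes, zero fill."""
    dy, dx = int(offset[0]), int(offset[1])
    out = np.zeros_like(frame)
    ny, nx = frame.shape[-2:]
    ys = slice(max(dy, 0), min(ny, ny + dy))
    xs = slice(max(dx, 0), min(nx, nx + dx))
    ys_src = slice(max(-dy, 0), min(ny, ny - dy))
    xs_src = slice(max(-dx, 0), min(nx, nx - dx))
    out[..., ys, xs] = frame[..., ys_src, xs_src]
    return out


# --------------------------------------------------------------------------
# fixed sections
# --------------------------------------------------------------------------


def _band_boundary(
    rng: np.random.Generator, nx: int, y_mean: float, amp: float
) -> np.ndarray:
    """Smooth sinusoidal band boundary y(x), sampled at 65 x positions."""
    xs = np.linspace(0, nx - 1, 65)
    phase = rng.uniform(0, 2 * np.pi)
    ys = y_mean + amp * np.sin(2 * np.pi * xs / nx * 1.3 + phase)
    return np.stack([xs, ys], axis=1)


def _band_polygon(
    upper: np.ndarray | None, lower: np.ndarray | None, ny: int, nx: int
) -> np.ndarray:
    """Polygon between two boundaries (or an image edge if None)."""
    if upper is None:
        top = np.array([[0.0, 0.0], [nx - 1.0, 0.0]])
    else:
        top = upper
    if lower is None:
        bottom = np.array([[nx - 1.0, ny - 1.0], [0.0, ny - 1.0]])
    else:
        bottom = lower[::-1]
    return np.concatenate([top, bottom], axis=0)


def _points_in_polygon_band(
    rng: np.random.Generator,
    n: int,
    roi: LayerROI,
    placement: str,
    ny: int,
    nx: int,
    margin: float,
) -> np.ndarray:
    """Place ~n soma centers (y, x) inside a layer polygon."""
    shp = roi.shapely
    if n <= 0 or shp.area <= 0:
        return np.zeros((0, 2))
    x0, y0, x1, y1 = shp.bounds
    x0, y0 = max(x0, margin), max(y0, margin)
    x1, y1 = min(x1, nx - margin), min(y1, ny - margin)
    if placement == "poisson":
        pts: list[tuple[float, float]] = []
        tries = 0
        while len(pts) < n and tries < 200 * n:
            tries += 1
            py, px = rng.uniform(y0, y1), rng.uniform(x0, x1)
            if shp.contains(__import__("shapely.geometry", fromlist=["Point"]).Point(px, py)):
                pts.append((py, px))
        return np.array(pts) if pts else np.zeros((0, 2))
    # perturbed grid sized so the in-polygon count approximates n
    s = float(np.sqrt(shp.area / n))
    from shapely.geometry import Point as _Point

    pts = []
    yy = y0 + s / 2
    while yy < y1:
        xx = x0 + s / 2
        while xx < x1:
            py = yy + rng.uniform(-0.2, 0.2) * s
            px = xx + rng.uniform(-0.2, 0.2) * s
            if shp.contains(_Point(px, py)):
                pts.append((py, px))
            xx += s
        yy += s
    return np.array(pts) if pts else np.zeros((0, 2))


def _draw_microglia_2p5d(
    rng: np.random.Generator,
    volume: np.ndarray,
    center_yx: tuple[float, float],
    cfg: SynthConfig,
    arbor: bool,
) -> None:
    """Soma sphere plus a flat process arbor at the soma's z plane."""
    nz, ny, nx = volume.shape
    cz = int(rng.uniform(nz * 0.25, nz * 0.75))
    r = cfg.soma_radius_um / cfg.voxel_size_um[1]
    v = _sphere_coords((cz, center_yx[0], center_yx[1]), r, (nz, ny, nx))
    volume[v[:, 0], v[:, 1], v[:, 2]] = True
    if not arbor:
        return
    length_px = cfg.process_length_um / cfg.voxel_size_um[1]
    for _ in range(cfg.n_processes):
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.sin(theta), np.cos(theta)])
        pos = np.array(center_yx, float) + direction * (r + 1)
        target = int(rng.uniform(0.6, 1.2) * length_px)
        z = cz
        for _ in range(target):
            jitter = rng.normal(scale=0.5, size=2)
            step = direction + jitter
            step = np.round(step / (np.abs(step).max() + 1e-9))
            pos = pos + step
            direction = 0.75 * direction + 0.25 * step
            direction /= np.linalg.norm(direction) + 1e-9
            if rng.random() < 0.1:
                z = int(np.clip(z + rng.integers(-1, 2), 0, nz - 1))
            iy, ix = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= iy < ny and 0 <= ix < nx):
                break
            volume[z, iy, ix] = True


def generate_fixed_section(
    config: SynthConfig,
) -> tuple[SectionImage, dict[str, LayerROI], GroundTruth]:
    """Generate a fixed cerebellar section with layered lobule geometry.

    The (y, x) plane is split into three curved bands — ML+PCL on top,
    GL in the middle, WM at the bottom — by sinusoidal boundaries.
    Microglia somas are placed per-layer at the configured density
    (perturbed grid or Poisson), Purkinje somas along a curved PCL path
    at the configured spacing, and Purkinje dendrites ascend into the
    ML band. Group effects scale densities and spacings multiplicatively.
    """
    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    nz = config.fixed_n_slices
    vz, vy, vx = config.voxel_size_um

    b1 = _band_boundary(rng, nx, 0.45 * ny, 0.05 * ny)  # ML+PCL / GL
    b2 = _band_boundary(rng, nx, 0.75 * ny, 0.04 * ny)  # GL / WM
    depth_um = nz * vz
    rois = {
        "ML+PCL": LayerROI("ML+PCL", _band_polygon(None, b1, ny, nx), (vy, vx), depth_um=depth_um),
        "GL": LayerROI("GL", _band_polygon(b1, b2, ny, nx), (vy, vx), depth_um=depth_um),
        "WM": LayerROI("WM", _band_polygon(b2, None, ny, nx), (vy, vx), depth_um=depth_um),
    }

    # --- microglia somas per layer ----------------------------------------
    mic = np.zeros((nz, ny, nx), dtype=bool)
    mic_somas: dict[str, np.ndarray] = {}
    margin = config.soma_radius_um / vy + 2
    for label, roi in rois.items():
        dens = config.microglia_density_per_layer.get(label, 0.0)
        dens *= config.effect("microglia_density")
        n = int(round(dens * roi.area_um2))
        centers = _points_in_polygon_band(
            rng, n, roi, config.placement, ny, nx, margin
        )
        mic_somas[label] = centers
        for cy, cx in centers:
            _draw_microglia_2p5d(rng, mic, (cy, cx), config, config.microglia_arbors)

    # --- Purkinje somas along the PCL path --------------------------------
    r_ps = config.purkinje_soma_radius_um / vy
    path = b1.copy()
    path[:, 1] -= r_ps + 1.0  # somas sit just above the ML/GL boundary
    spacing_px = config.pcl_soma_spacing_um / vx
    spacing_px /= config.effect("pcl_linear_density")

    purk = np.zeros((nz, ny, nx), dtype=bool)
    seg_vec = np.diff(path, axis=0)
    seg_len = np.hypot(seg_vec[:, 0], seg_vec[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total_len = cum[-1]
    soma_positions = []
    s = spacing_px * rng.uniform(0.3, 0.7)
    while s < total_len:
        i = int(np.searchsorted(cum, s) - 1)
        frac = (s - cum[i]) / max(seg_len[i], 1e-9)
        px, py = path[i] + frac * seg_vec[i]
        soma_positions.append((py, px))
        s += spacing_px * (1.0 + rng.uniform(-0.1, 0.1))
    soma_positions = np.array(soma_positions) if soma_positions else np.zeros((0, 2))
    cz_mid = nz // 2
    for py, px in soma_positions:
        v = _sphere_coords((cz_mid, py, px), r_ps, (nz, ny, nx))
        purk[v[:, 0], v[:, 1], v[:, 2]] = True
        # dendritic trunk ascending into the ML band
        y, x = py - r_ps, px
        lateral = 0.0
        for _ in range(int(0.35 * ny)):
            y -= 1.0
            x += rng.normal(scale=0.4) + lateral
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < ny and 0 <= ix < nx):
                break
            z0 = max(0, cz_mid - 2)
            purk[z0 : cz_mid + 2, iy, ix] = True
            if rng.random() < 0.05:
                lateral = rng.uniform(-0.3, 0.3)

    # --- emit --------------------------------------------------------------
    img = np.zeros((nz, 2, ny, nx), dtype=np.float32)
    img[:, MICROGLIA] = AMPLITUDE * mic
    img[:, PURKINJE] = AMPLITUDE * purk
    img[:, MICROGLIA] += config.bleed_alpha * img[:, PURKINJE]
    if config.noise_sd > 0:
        img += rng.normal(scale=config.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0, None, out=img)

    from skimage.draw import polygon2mask

    layer_masks = {
        label: polygon2mask((ny, nx), roi.polygon[:, ::-1]) for label, roi in rois.items()
    }
    path_len_um = polyline_length_um(path, (vy, vx))
    truth = GroundTruth(
        microglia_somas=mic_somas,
        purkinje_somas=soma_positions,
        pcl_path=path,
        layer_masks=layer_masks,
        params={
            "pcl_length_um": path_len_um,
            "n_purkinje_somas": len(soma_positions),
            "true_linear_frequency": len(soma_positions) / path_len_um,
            # intended (pre-discretization) linear density: effects scale
            # this exactly even when realized counts quantize
            "intended_linear_frequency": config.effect("pcl_linear_density")
            / config.pcl_soma_spacing_um,
            "spacing_px": spacing_px,
            "effects": {
                "pcl_linear_density": config.effect("pcl_linear_density"),
                "microglia_density": config.effect("microglia_density"),
            },
        },
    )
    return (
        SectionImage(data=img, voxel_size_um=config.voxel_size_um),
        rois,
        truth,
    )


# --------------------------------------------------------------------------
# laser-ablation injury series
# --------------------------------------------------------------------------


def _circle_polygon(cy: float, cx: float, radius: float, n: int = 90) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack(
        [cx + radius * np.cos(theta), cy + radius * np.sin(theta)], axis=1
    )


def generate_injury_series(config: SynthConfig):
    """Generate a laser-ablation series with a converging microglia front.

    A fixed autofluorescent core disk sits at the field center; the
    microglia occupy a sealed annulus whose inner radius shrinks toward
    the core at ``injury_rate_px`` per interval, so the true front
    polygon shrinks monotonically. Returns the stack plus an
    :class:`~cerequant.dynamics.InjurySeries` ground truth with analytic
    circle-area proximities.
    """
    from .dynamics import InjurySeries

    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    nt = config.n_timepoints
    nz = 8
    cy, cx = ny / 2.0, nx / 2.0
    rc = config.injury_core_radius_px
    r0 = config.injury_front_radius_px
    r_out = min(ny, nx) / 2.0 - 2
    if rc >= r_out or r0 > r_out:
        raise ValueError("injury core/front must lie inside the field")

    yy, xx = np.mgrid[0:ny, 0:nx]
    rr = np.hypot(yy - cy, xx - cx)
    core2d = rr <= rc

    img = np.zeros((nt, nz, 2, ny, nx), dtype=np.float32)
    front_polys = []
    radii = []
    for t in range(nt):
        rt = max(rc, r0 - config.injury_rate_px * t)
        radii.append(rt)
        ring = (rr >= rt) & (rr <= r_out)
        mask3d = np.zeros((nz, ny, nx), dtype=bool)
        mask3d[2:6] = ring
        img[t, :, MICROGLIA] += AMPLITUDE * mask3d
        img[t, :, MICROGLIA] += AMPLITUDE * core2d  # autofluorescent core
        img[t, :, PURKINJE] += AMPLITUDE * core2d
        front_polys.append(_circle_polygon(cy, cx, rt))
    if config.noise_sd > 0:
        img += rng.normal(scale=config.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0, None, out=img)

    radii = np.array(radii)
    denom = r0**2 - rc**2
    proximity = (radii**2 - rc**2) / denom if denom > 0 else np.ones(nt)
    truth = InjurySeries(
        core_polygon=_circle_polygon(cy, cx, rc),
        front_polygons=front_polys,
        proximity=proximity,
    )
    stack = TimelapseStack(
        data=img, voxel_size_um=config.voxel_size_um, dt_min=config.dt_min
    )
    return stack, truth


# --------------------------------------------------------------------------
# occupancy-controlled 3-D regions (volume-fraction and interaction tests)
# --------------------------------------------------------------------------


def _fill_to_occupancy(
    rng: np.random.Generator, shape: tuple[int, int, int], occupancy: float
) -> np.ndarray:
    """Random somas + process segments filling exactly round(occ * volume) voxels."""
    nz, ny, nx = shape
    target = int(round(occupancy * nz * ny * nx))
    mask = np.zeros(shape, dtype=bool)
    total = 0
    while total < target:
        if rng.random() < 0.25:  # soma-like blob
            c = (rng.uniform(2, nz - 2), rng.uniform(4, ny - 4), rng.uniform(4, nx - 4))
            v = _sphere_coords(c, rng.uniform(2.5, 4.0), shape)
        else:  # process-like segment
            p0 = np.array([rng.uniform(0, nz), rng.uniform(0, ny), rng.uniform(0, nx)])
            d = rng.normal(size=3)
            d[0] *= 0.3  # mostly in-plane
            d /= np.linalg.norm(d) + 1e-9
            length = rng.uniform(20, 60)
            npts = int(length * 2)
            pts = p0[None] + np.linspace(0, length, npts)[:, None] * d[None]
            pts = np.round(pts).astype(int)
            keep = (
                (pts[:, 0] >= 0) & (pts[:, 0] < nz)
                & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
                & (pts[:, 2] >= 0) & (pts[:, 2] < nx)
            )
            v = np.unique(pts[keep], axis=0)
        if v.size == 0:
            continue
        new = v[~mask[v[:, 0], v[:, 1], v[:, 2]]]
        if new.size == 0:
            continue
        excess = total + len(new) - target
        if excess > 0:
            drop = rng.permutation(len(new))[:excess]
            new = np.delete(new, drop, axis=0)
        mask[new[:, 0], new[:, 1], new[:, 2]] = True
        total += len(new)
    return mask


def generate_volume_region(
    config: SynthConfig,
    occupancy: float,
    shape: tuple[int, int, int] = (51, 256, 256),
    purkinje_occupancy: float = 0.0,
) -> tuple[SectionImage, GroundTruth]:
    """Generate a 3-D layer region whose microglia voxel fraction is exact.

    Used to reproduce the sparse-occupancy regime of the deep cerebellar
    layers (microglia volume fractions of order 1e-2 and below) with a
    ground-truth voxel count equal to ``round(occupancy * volume)``.
    """
    if not (0 <= occupancy < 1):
        raise ValueError("occupancy must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    mic = _fill_to_occupancy(rng, shape, occupancy)
    img = np.zeros((shape[0], 2, shape[1], shape[2]), dtype=np.float32)
    img[:, MICROGLIA] = AMPLITUDE * mic
    if purkinje_occupancy > 0:
        purk = _fill_to_occupancy(rng, shape, purkinje_occupancy)
        img[:, PURKINJE] = AMPLITUDE * purk
        img[:, MICROGLIA] += config.bleed_alpha * img[:, PURKINJE]
    else:
        purk = np.zeros(shape, dtype=bool)
    if config.noise_sd > 0:
        img += rng.normal(scale=config.noise_sd, size=img.shape).astype(np.float32)
        np.clip(img, 0, None, out=img)
    truth = GroundTruth(
        microglia_masks=mic[None],
        purkinje_mask=purk,
        params={
            "occupancy": occupancy,
            "n_voxels": int(mic.sum()),
            "purkinje_occupancy": purkinje_occupancy,
        },
    )
    return SectionImage(data=img, voxel_size_um=config.voxel_size_um), truth


def generate_overlap_volume(
    shape: tuple[int, int, int],
    occupancy: float,
    overlap_fraction: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Microglia mask plus a Purkinje mask covering a set fraction of it.

    The Purkinje mask contains exactly ``round(overlap_fraction * |mic|)``
    microglia voxels plus additional voxels outside the microglia mask,
    so the expected normalized interaction equals ``overlap_fraction``.
    """
    rng = np.random.default_rng(seed)
    mic = _fill_to_occupancy(rng, shape, occupancy)
    mic_idx = np.argwhere(mic)
    n_overlap = int(round(overlap_fraction * len(mic_idx)))
    chosen = mic_idx[rng.permutation(len(mic_idx))[:n_overlap]]
    purk = _fill_to_occupancy(rng, shape, occupancy)  # independent background
    purk &= ~mic  # remove chance overlap, then add the controlled overlap
    purk[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return mic, purk
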