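"""End-to-end orchestration and group summaries.

``run_invivo`` executes the full time-lapse chain — drift correction,
bleed-through subtraction, temporal PCA denoising, ML/PCL layer
substacks, binarization, motility/surveillance, Sholl curves, and
microglia–Purkinje interaction metrics — and returns a long-format
metric table. ``run_fixed`` covers the fixed-tissue chain: per-layer
density, whole-lobule spacing index, Purkinje linear frequency, and 3-D
interaction metrics, averaged over sections. ``group_summary`` reduces a
metric table to group means ± SEM and percent differences.

Inferential statistics (ANOVA, post-hoc tests) are deliberately out of
scope; the metric table is exported for external statistical software.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interactions as ix
from .containers import MICROGLIA, PURKINJE, LayerROI, SomaSet
from .dynamics import motility_index
from .preprocess import (
    correct_drift,
    estimate_bleedthrough,
    max_project,
    pca_denoise,
    split_layers,
    subtract_bleedthrough,
)
from .segment import binarize_objects, classify_subcomponents, detect_somas
from .sholl import sholl_intersections
from .spatial import density, linear_frequency, spacing_index
from .synthgen import (
    AMPLITUDE,
    SynthConfig,
    generate_fixed_section,
    generate_timelapse,
)

log = logging.getLogger("cerequant")

METRIC_COLUMNS = [
    "animal",
    "sex",
    "treatment",
    "section",
    "layer",
    "metric",
    "value",
    "units",
]


@dataclass
class RunConfig:
    """Pipeline run configuration; round-trips through YAML."""

    mode: str = "synth"  # invivo | fixed | injury | synth
    synth: SynthConfig = field(default_factory=SynthConfig)
    input_paths: list[str] = field(default_factory=list)
    threshold: float = AMPLITUDE / 2
    min_size: int = 4
    max_size: int | None = None
    # near-full temporal rank: aggressive truncation erodes pixels that are
    # present in only one or two frames and biases the motility index down
    pca_components: int = 10
    pcl_start_z: int | None = None
    layer_slices: int | None = None
    n_sections: int = 3
    animal_id: str = "synth_01"
    out_dir: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        synth = d.pop("synth", {})
        for key in ("image_shape", "voxel_size_um"):
            if key in synth and synth[key] is not None:
                synth[key] = tuple(synth[key])
        return cls(synth=SynthConfig(**synth), **d)


def _row(config: RunConfig, section, layer, metric, value, units) -> dict:
    return {
        "animal": config.animal_id,
        "sex": config.synth.sex,
        "treatment": config.synth.treatment,
        "section": section,
        "layer": layer,
        "metric": metric,
        "value": float(value),
        "units": units,
    }


def run_invivo(config: RunConfig) -> pd.DataFrame:
    """Full in-vivo chain on a synthetic (or loaded) time-lapse stack.

    Returns a long-format metric table; Sholl curves are attached under
    ``table.attrs["sholl_curves"]``.
    """
    if config.mode == "synth" or not config.input_paths:
        cfg = config.synth.replace(seed=config.seed + config.synth.seed)
        stack, truth = generate_timelapse(cfg)
    else:
        from .io import read_stack

        stack = read_stack(config.input_paths[0])
        truth = None
    log.info("invivo stage=load shape=%s", stack.data.shape)

    stack, drift = correct_drift(stack)
    log.info("invivo stage=drift offsets=%s", drift.offsets.tolist())

    # Purkinje-only voxels for bleed estimation: bright in the Purkinje
    # channel at t=1 and dark in a rough microglia binarization
    purk0 = stack.data[0, :, PURKINJE]
    mic0 = stack.data[0, :, MICROGLIA]
    purk_only = (purk0 >= config.threshold) & ~(
        mic0 >= config.threshold * (1 + config.synth.bleed_alpha)
    )
    bleed = estimate_bleedthrough(
        stack.copy_with(stack.data[:1]), purk_only
    )
    stack = subtract_bleedthrough(stack, bleed)
    log.info("invivo stage=bleed alpha=%.4f", bleed.alpha)

    stack = pca_denoise(stack, config.pca_components)

    nz = stack.n_slices
    pcl_start = (
        config.pcl_start_z
        if config.pcl_start_z is not None
        else (truth.layer_z["PCL"][0] if truth else int(0.65 * nz))
    )
    n_slices = (
        config.layer_slices
        if config.layer_slices is not None
        else min(pcl_start, nz - pcl_start)
    )
    ml, pcl = split_layers(stack, pcl_start, n_slices)
    log.info("invivo stage=split pcl_start=%d n_slices=%d", pcl_start, n_slices)

    rows = []
    curves = {}
    # bleed subtraction shifts the background mode; use a threshold at
    # half the emission amplitude relative to the corrected background
    thr = config.threshold
    for layer_name, sub in (("ML", ml), ("PCL", pcl)):
        proj = max_project(sub)  # (T, C, Y, X)
        masks = [
            binarize_objects(proj[t, MICROGLIA], thr, config.min_size).data
            for t in range(sub.n_timepoints)
        ]
        dyn = motility_index(masks, layer=layer_name)
        rows.append(_row(config, None, layer_name, "motility_index", dyn.motility_index, "dimensionless"))
        rows.append(_row(config, None, layer_name, "motility_index_pooled", dyn.motility_index_pooled, "dimensionless"))
        rows.append(_row(config, None, layer_name, "surveillance_ratio", dyn.surveillance_ratio, "dimensionless"))

        # Sholl on the first timepoint: the soma nearest the field center
        somas = detect_somas(masks[0], soma_min_size=10)
        if len(somas):
            center = np.array(masks[0].shape) / 2
            idx = int(np.argmin(np.linalg.norm(somas.coords - center, axis=1)))
            cy, cx = somas.coords[idx]
            curve = sholl_intersections(
                masks[0],
                (cy, cx),
                max_radius_um=70.0,
                pixel_size_um=stack.voxel_size_um[2],
                cell_id=f"{config.animal_id}_{layer_name}",
                animal_id=config.animal_id,
                layer=layer_name,
                treatment=config.synth.treatment,
                sex=config.synth.sex,
            )
            curves[layer_name] = curve
            rows.append(_row(config, None, layer_name, "sholl_max_intersections", curve.intersections.max(), "count"))

        # 3-D interactions per timepoint
        mic3d = [
            binarize_objects(sub.data[t, :, MICROGLIA], thr, config.min_size).data
            for t in range(sub.n_timepoints)
        ]
        purk3d = [
            binarize_objects(sub.data[t, :, PURKINJE], thr, config.min_size).data
            for t in range(sub.n_timepoints)
        ]
        region_voxels = sub.data[0, :, 0].size
        vf_mic = np.mean([ix.volume_fraction(m, region_voxels) for m in mic3d])
        vf_purk = np.mean([ix.volume_fraction(p, region_voxels) for p in purk3d])
        rows.append(_row(config, None, layer_name, "volume_fraction_microglia", vf_mic, "fraction"))
        rows.append(_row(config, None, layer_name, "volume_fraction_purkinje", vf_purk, "fraction"))
        inter_masks, ov_counts, mic_counts = [], [], []
        for m, p in zip(mic3d, purk3d):
            omask, count = ix.interaction_overlap(m, p)
            inter_masks.append(omask.data)
            ov_counts.append(count)
            mic_counts.append(int(m.sum()))
        ni = ix.normalized_interaction(np.array(ov_counts), np.array(mic_counts))
        rows.append(_row(config, None, layer_name, "normalized_interaction", ni, "fraction"))
        if any(m.any() for m in inter_masks):
            try:
                dii = ix.dynamic_interaction_index(inter_masks)
                rows.append(_row(config, None, layer_name, "dynamic_interaction_index", dii.motility_index, "dimensionless"))
            except ValueError:
                pass
        rows.append(_row(config, None, layer_name, "coverage_index", ix.coverage_index(inter_masks), "fraction"))

    table = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    table.attrs["sholl_curves"] = curves
    table.attrs["drift_offsets"] = drift.offsets
    table.attrs["bleed_alpha"] = bleed.alpha
    if config.out_dir:
        _write_outputs(config, table)
    return table


def run_fixed(config: RunConfig) -> pd.DataFrame:
    """Fixed-tissue chain over ``n_sections`` synthetic sections.

    Computes per-layer microglia density, whole-lobule spacing index,
    Purkinje cell linear frequency along the ground-truth PCL path (the
    stand-in for the manually drawn segmented line), and per-layer 3-D
    interaction metrics; per-animal values are the equal-weight mean over
    sections.
    """
    rows = []
    thr = config.threshold
    for s in range(config.n_sections):
        cfg = config.synth.replace(seed=config.seed + 1000 * config.synth.seed + s)
        section, rois, truth = generate_fixed_section(cfg)
        ny, nx = cfg.image_shape
        vz, vy, vx = cfg.voxel_size_um
        mic_proj = max_project(section.data[:, MICROGLIA], z_axis=0)
        mic_mask = binarize_objects(mic_proj, thr, config.min_size).data
        somas = detect_somas(mic_mask, soma_min_size=10)
        whole = LayerROI(
            "lobule",
            np.array([[0, 0], [nx - 1, 0], [nx - 1, ny - 1], [0, ny - 1]], float),
            (vy, vx),
        )
        rows.append(_row(config, s, "lobule", "microglia_density", density(somas, whole), "per_um2"))
        if len(somas) >= 2:
            rows.append(_row(config, s, "lobule", "spacing_index", spacing_index(somas, whole), "dimensionless"))
        for label, roi in rois.items():
            rows.append(_row(config, s, label, "microglia_density", density(somas, roi), "per_um2"))

        # Purkinje linear frequency along the PCL path
        purk_proj = max_project(section.data[:, PURKINJE], z_axis=0)
        purk_mask = binarize_objects(purk_proj, thr, min_size=10).data
        r_soma_px = cfg.purkinje_soma_radius_um / vy
        psomas = detect_somas(
            purk_mask,
            soma_min_size=int(np.pi * (0.6 * r_soma_px) ** 2),
            opening_radius=max(2, int(0.55 * r_soma_px)),
        )
        lf = linear_frequency(
            psomas, truth.pcl_path, (vy, vx), band_um=2 * cfg.purkinje_soma_radius_um
        )
        rows.append(_row(config, s, "PCL", "linear_frequency", lf, "per_um"))

        # 3-D interactions per layer (GL excluded)
        mic3d = binarize_objects(section.data[:, MICROGLIA], thr, config.min_size).data
        purk3d = binarize_objects(section.data[:, PURKINJE], thr, config.min_size).data
        for label in ("ML+PCL", "WM"):
            lmask = truth.layer_masks[label]
            region = np.broadcast_to(lmask, mic3d.shape)
            vf_mic = ix.volume_fraction(mic3d & region, int(region.sum()))
            vf_purk = ix.volume_fraction(purk3d & region, int(region.sum()))
            rows.append(_row(config, s, label, "volume_fraction_microglia", vf_mic, "fraction"))
            rows.append(_row(config, s, label, "volume_fraction_purkinje", vf_purk, "fraction"))
            _, count = ix.interaction_overlap(mic3d & region, purk3d & region)
            mcount = int((mic3d & region).sum())
            if mcount:
                rows.append(_row(config, s, label, "normalized_interaction", count / mcount, "fraction"))
    table = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    # per-animal value: mean over the sections
    means = (
        table.groupby(["animal", "sex", "treatment", "layer", "metric", "units"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    means["section"] = "mean"
    table = pd.concat([table, means[METRIC_COLUMNS]], ignore_index=True)
    if config.out_dir:
        _write_outputs(config, table)
    return table


def group_summary(
    table: pd.DataFrame,
    metric: str,
    layer: str | None = None,
    by_sex: bool = False,
    control: str = "saline",
    treated: str = "ethanol",
) -> pd.DataFrame:
    """Group means ± SEM and the percent difference treated vs control.

    Percent difference is ``100 * (1 - mean_treated / mean_control)``, so
    a positive value is a reduction. SEM is reported as NaN (absent) for
    single-member groups.
    """
    sub = table[table["metric"] == metric]
    if layer is not None:
        sub = sub[sub["layer"] == layer]
    if "section" in sub.columns and (sub["section"] == "mean").any():
        sub = sub[sub["section"] == "mean"]
    if sub.empty:
        raise ValueError(f"no rows for metric {metric!r}")
    keys = ["treatment", "sex"] if by_sex else ["treatment"]
    rows = []
    for key, grp in sub.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["value"].to_numpy(float)
        if len(vals) == 0:
            raise ValueError(f"empty group {key}")
        rows.append(
            dict(
                zip(keys, key),
                mean=float(vals.mean()),
                sem=float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                n=len(vals),
            )
        )
    out = pd.DataFrame(rows)
    pct = []
    for _, r in out.iterrows():
        if r["treatment"] != treated:
            pct.append(float("nan"))
            continue
        sel = out["treatment"] == control
        if by_sex:
            sel &= out["sex"] == r["sex"]
        if not sel.any() or out.loc[sel, "mean"].iloc[0] == 0:
            pct.append(float("nan"))
        else:
            pct.append(100.0 * (1.0 - r["mean"] / out.loc[sel, "mean"].iloc[0]))
    out["percent_reduction_vs_control"] = pct
    return out


def _write_outputs(config: RunConfig, table: pd.DataFrame) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "metrics.csv", index=False)
    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "threshold": config.threshold,
        "bleed_alpha": float(table.attrs.get("bleed_alpha", float("nan"))),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
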