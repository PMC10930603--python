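# cerequant

Quantification of cerebellar microglia and Purkinje cells from
two-photon time-lapse and fixed-tissue confocal image stacks, with a
synthetic-data generator that makes every measurement stage testable
against known ground truth.

## Who this is for

Labs that image GFP-labeled microglia and tdTomato-labeled Purkinje
cells in cerebellar lobules — in vivo (two-channel TZCYX time-lapse
z-stacks, 12 timepoints at 5-min intervals, 1 µm z-step) or in fixed
sagittal sections (two-channel confocal z-stacks with layer ROIs) — and
want a reproducible, scriptable alternative to interactive
FIJI/Ilastik/Cellpose workflows for the standard measurement battery:

- **Preprocessing**: blinding, integer-pixel drift correction
  (phase cross-correlation of z max projections), channel bleed-through
  estimation and subtraction, modal background correction, temporal PCA
  denoising, ML/PCL layer substacks.
- **Microglia dynamics**: motility index
  `M.I. = (extended + retracted) / stable` pixels between consecutive
  binarized timepoints, and surveillance ratio
  `S.R. = |∪ₜ maskₜ| / |mask₁|`.
- **Morphology**: Sholl ring-intersection curves (2 µm rings, 70 µm in
  vivo / 100 µm fixed) and a hierarchical Bayesian change-point model
  `log E[I(r)] = τ + α₁(r − γ)` for `r ≤ γ`, `τ + α₂(r − γ)` beyond,
  with Poisson counts; cells nest in animals, animals in
  treatment-by-sex groups, and effects are reported as 95% credible
  intervals.
- **Injury response**: microglia-front polygon detection around a laser
  ablation core and the normalized proximity
  `(A_front(t) − A_core) / (A_front(1) − A_core)`.
- **Spatial statistics**: per-layer soma density, nearest-neighbor
  spacing index `(mean NN distance)² × density` (1 for a grid, 0.25 for
  Poisson), and Purkinje cell linear frequency (somas per µm of the PCL
  path).
- **Cell–cell interactions**: volume fractions, 3-D binarized overlap,
  normalized interaction (overlap per microglia voxel, averaged over
  timepoints/sections), dynamic interaction index, and coverage index.

Segmentation uses deterministic surrogates (thresholding with
connected-component size exclusion, morphological opening for somas,
skeleton branch-point detection) in place of interactively trained
classifiers, so the whole pipeline is reproducible bit-for-bit from a
seed.

## Worked example

Simulate six fixed sections per treatment group with an 8% reduction in
Purkinje-cell linear density injected into the ethanol group, run soma
detection and linear frequency, and summarize:

```python
import pandas as pd
from cerequant.pipeline import RunConfig, group_summary, run_fixed
from cerequant.synthgen import SynthConfig

tables = []
for g, treat in enumerate(("saline", "ethanol")):
    for s in range(6):
        cfg = RunConfig(
            n_sections=1, animal_id=f"{treat}_s{s}", seed=1 + 1000 * g + 7 * s,
            synth=SynthConfig(image_shape=(256, 1024), fixed_n_slices=8,
                              noise_sd=5.0, treatment=treat,
                              group_effects={"ethanol": {"pcl_linear_density": 0.92}},
                              seed=3))
        tables.append(run_fixed(cfg))
table = pd.concat(tables, ignore_index=True)
print(group_summary(table, "linear_frequency", layer="PCL").to_string(index=False))
```

```
treatment     mean      sem  n  percent_reduction_vs_control
  ethanol 0.030548 0.000207  6                      8.291522
   saline 0.033310 0.000162  6                           NaN
```

The saline group measures ~0.0333 Purkinje somas per µm of PCL path
(one soma per ~30 µm); the pipeline recovers the injected 8% reduction
as an 8.3% measured drop.

A command-line interface wraps the same library:

```bash
cerequant synth --preset fixed --out demo/ --seed 1   # TIFF + ROI JSON
cerequant run --mode synth --out demo_run/ --seed 1   # metric table CSV
```

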