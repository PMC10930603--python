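# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `cerequant`. All quantities named here are computed by
the test suite or by `scripts/acceptance.py`; nothing below is an
empirical claim beyond what those runs produce.

## Synthetic-data generator

The generator (`cerequant.synthgen`) emulates the acquisition geometry of
two-photon cerebellar imaging: two channels (microglia, Purkinje), 12
timepoints at 5-min intervals, z-stacks at 1 µm step (101 µm deep by
default), with the molecular layer (ML) above the Purkinje cell layer
(PCL) along z. Fixed sections are single-timepoint z-stacks whose (y, x)
plane is divided into three curved bands — ML+PCL, granule layer (GL),
white matter (WM) — by sinusoidal boundaries, with the PCL path running
just above the ML/GL boundary.

**Microglia** are branched skeletons: a static soma sphere (3.5 µm radius
by default) plus 4 process branches grown as persistent random walks
(~25 µm), with branch voxels occupying (y, x) positions unique within a
cell so that the z max projection is injective. **Process dynamics** are
tip turnover: per interval, `r` tip pixels are retracted and `r` new tip
pixels extended, with `r = m·N/(2 + m)` chosen so the expected motility
index of each transition equals the configured turnover `m` (`N` is the
cell's projected pixel count, since motility is measured on max
projections). A pixel retracted in an interval may not be re-extended in
the same interval, otherwise the transition would register no change.
This is a measurement-calibration model, not a biophysical one: real
microglia remodel with spatial correlation, process-level coordination,
and velocity structure that this model deliberately omits. Passing
turnover-recovery tests therefore validates the measurement chain, not
any biological model of motility.

**Purkinje cells** are soma spheres (7 µm radius) in a jittered monolayer
at the ML/PCL boundary (in vivo) or spaced along the curved PCL path at
`pcl_soma_spacing_um` (default 30 µm, roughly one soma per 30 µm of
path, the right order for adult mouse PCL), with quasi-planar bifurcating
dendritic arbors ascending through the ML.

**Image formation**: labeled voxels emit at a constant amplitude (1000);
the Purkinje channel times `bleed_alpha` is added to the microglia
channel; integer random-walk drift is applied per timepoint; Gaussian
noise (sd 10 by default) is added last and clipped at zero. Ground truth
is pre-noise and pre-drift, so thresholding a noise-free, drift-free
stack at the emission amplitude reproduces the ground-truth masks
exactly. There is no PSF, photobleaching, photon (shot) noise, or
non-microglial autofluorescence except the injury core; tests passing on
this generator say nothing about segmentation robustness to those
effects.

**Group effects** are multiplicative factors on generator parameters,
keyed by treatment (`"ethanol"`), treatment:sex (`"ethanol:F"`), or sex
(`"*:F"`). The ground truth records the *intended* (pre-discretization)
parameter values, so an injected effect is recoverable exactly from
ground truth even when realized counts quantize.

**Soma placement** is a perturbed grid by default (±20% jitter), which
produces the near-regular pattern real microglia show (spacing index near
1); a Poisson mode provides the null regime (spacing index 0.25) used for
closed-form tests.

**Occupancy regions** (`generate_volume_region`) fill a 3-D volume with
soma-like blobs and process-like segments to an exact voxel count
`round(occupancy × volume)`, for volume-fraction calibration in the
sparse regimes typical of cerebellar microglia (fractions of order
10⁻³–10⁻²).

## Preprocessing

- **Drift** is estimated at integer-pixel resolution by phase
  cross-correlation of the microglia channel's z max projections against
  timepoint 1, and applied to both channels with zero-padded edges. No
  sub-pixel or nonrigid registration. On generator data the injected
  integer offsets are recovered exactly and correction is idempotent.
- **Background** per timepoint and channel is the frame's modal
  intensity — robust because tissue background dominates pixel counts.
- **Bleed-through** `alpha` is the least-squares *through-origin* slope
  of microglia on Purkinje intensity over a Purkinje-only mask, after
  modal-background subtraction of both channels. Forcing the line
  through the origin keeps the slope identifiable when the masked
  Purkinje signal is nearly uniform (as it is for a bright, saturating
  label); it is invariant to uniform brightness rescaling. Alpha is
  estimated per stack, not per animal.
- **Denoising** is temporal PCA: each channel unfolded to
  (timepoints × pixels), mean-centered over time, reconstructed from the
  top-k components. Default `k = 10` of 12 timepoints: aggressive
  truncation (e.g. k = 6) visibly erodes pixels present in only one or
  two frames and biases the motility index downward, so near-full rank
  is the safe default for dynamics work.
- **Layer splitting** takes an explicit PCL-start slice (mirroring
  manual identification of the first Purkinje somas) and cuts equal
  half-open n-slice windows on both sides.

## Segmentation surrogates

Interactively trained pixel/object classifiers are replaced by
deterministic surrogates: thresholding with 8-/26-connected component
size exclusion; soma detection by morphological opening (disk/ball,
default radius 3 px) followed by size-filtered centroid extraction;
microglia soma/process partition by the same opening (exact partition by
construction); Purkinje branch points as skeleton pixels with ≥3
skeleton neighbors, dilated to radius 2. Size-exclusion bounds are
config-exposed; they have no canonical published values and must be set
per dataset.

## Dynamics

Motility index and surveillance ratio are pure set operations on
binarized 2-D masks, with no additional change-magnitude threshold.
"Stable" is the intersection of consecutive masks. Transitions with zero
stable pixels are excluded with a warning. Both a mean-over-transitions
M.I. (the default) and a pooled-pixel variant are reported, since either
aggregation is defensible; they agree on stationary sequences.

The injury front is the boundary polygon of the microglia-free connected
region containing the core centroid (the core's own pixels count as free
space, so an autofluorescent core does not split the region); manual
front polygons can be supplied instead. Normalized proximity uses
shoelace polygon areas.

## Sholl model and fit

Ring intersections are maximal foreground runs along Bresenham-rasterized
circles, ordered by angle and joined circularly; out-of-bounds ring
pixels count as background.

The change-point model is continuous at γ by construction (both branches
share τ at γ, so the fitted curve attains the branch maximum e^τ exactly
at the change-point). Counts are Poisson — the natural first choice for
intersection counts, and testable by simulation.

Fitting is two-stage:

1. **Per cell**: profile likelihood over γ on the ring-radius grid; at
   each candidate γ the remaining three parameters are Poisson MLEs
   (Newton/IRLS). The normalized profile gives γ's point estimate,
   variance, and a wide-interval flag (raised when the 95% interval
   spans >80% of the radius range, e.g. when α₁ ≈ α₂ and γ is
   unidentifiable — flagged, never a failure). The (τ, α₁, α₂)
   covariance comes from the observed information at the best γ
   (a Laplace approximation).
2. **Across cells**: each parameter gets an independent Gaussian
   hierarchy: cell estimates around animal means (variance σ²_cell plus
   the known per-cell estimation variance), animal means around a group
   regression (intercept + treatment + sex, optional interaction), with
   the animal random effect integrated out analytically
   (Sherman–Morrison). The posterior over regression coefficients and
   the two variance components (normal(0, s²) priors on coefficients,
   half-normal on the SDs, both scaled to the data's spread) is sampled
   with the emcee ensemble sampler (32 walkers, 1200 steps, 400 burn-in
   by default), seeded for bit-reproducibility. Convergence is checked
   by split-R̂ over four walker groups, threshold 1.05.

Treating stage-1 estimates as Gaussian pseudo-observations is the
standard meta-analytic approximation; it is accurate when each curve has
tens of informative rings, and degrades for near-empty curves (excluded:
fewer than two nonzero rings). Simulation tests verify intercept and
effect recovery and ~95% null coverage of the treatment-effect credible
intervals.

In-vivo Sholl (one cell per layer per animal) is supported as curves
only; model fitting is aimed at fixed-tissue sample sizes.

## Spatial statistics

Nearest-neighbor distances use no edge correction; for small ROIs this
biases the spacing index slightly upward (the Poisson simulation at
n = 1000 in a square lands near 0.258 rather than 0.250). Density
membership uses the even-odd rule with boundary points counted inside.
The spacing index is computed whole-lobule (per-layer optional). Somas
count toward linear frequency when their centroid lies within one soma
diameter (default band 15 µm) of the PCL polyline, since a drawn
segmented line has no published band width. Sections are averaged with
equal weight into animal values.

## Interactions

Overlap is a voxelwise AND of the two binarized channels, computed in
3-D (per timepoint in vivo, per 51-slice substack in fixed tissue);
normalized interaction averages overlap-per-microglia-voxel across
timepoints or sections, dropping (with a warning) entries with an empty
microglia mask. Subcomponent variants reuse the exact soma/process
partition, so subcomponent overlaps sum to the whole-cell overlap by
construction. The dynamic interaction index applies the motility-index
formula to max-projected interaction masks; the coverage index is the
union of interaction pixels over all timepoints per frame pixel. The GL
is excluded from interaction analysis (Purkinje axons are too sparse
there). In-vivo subcomponent overlaps are averaged per timepoint rather
than pooled across the hour, consistent with the whole-cell definition.

## Problem sizes

Default test and acceptance runs use desk-scale geometry chosen to keep
estimator behavior in the same regime as full-size data: in-vivo fields
of 96×96 µm with 40 z-planes and 12 timepoints; fixed sections of
256×1024 px for linear-frequency studies (~1 mm of PCL path, ~35 somas
per section, 10 sections per group); 512×512×51 volumes for
volume-fraction calibration; Sholl hierarchies of 2 groups × 5 animals ×
10 cells with 35 rings per curve. Group-effect recovery at ±2 percentage
points needs enough somas per section that count quantization (integer
somas on a finite path) stays below the tolerance; the ~35-soma sections
satisfy this, while very short paths would not.

## Known limitations

- No optical PSF, shot noise, photobleaching, or competing cell types in
  the generator; segmentation-robustness claims do not transfer.
- Drift correction is integer-pixel and rigid.
- The spacing index inherits the no-edge-correction bias above.
- The Sholl hierarchy assumes per-parameter independence across the four
  change-point parameters (their cross-covariances are dropped in
  stage 2).
- Inferential statistics (ANOVA, post-hoc testing) are intentionally
  excluded; the metric table is exported for external tools.
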