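# Methods

## The measurement model

A bright-field micrograph of submerged fungal culture shows dark
mycelium — spores early in a fermentation, elongated branching hyphae
mid-course, dense pellets late — on a bright medium with uneven
illumination. The package reduces each frame to one scalar, the
microscopic image intensity (MII), defined as the mean gray value of the
*transformed* frame in which background pixels are forced to zero and
mycelium pixels retain their (contrast-enhanced, inverted) signal. MII
therefore grows with both the area covered by mycelium and its optical
density, which is what makes it a biomass proxy.

Biomass calibration is simple linear regression of dry cell weight on
intensity, `DCW = β₀ + β₁·MII + ε` with Gaussian errors. β₀ (mg/L) is the
predicted DCW at zero intensity — in practice a small offset absorbing
medium turbidity — and β₁ (mg/L per intensity unit) is the optical gain
of the setup. Both are setup-specific: MII has no physical units, so a
calibration is only transferable across frames taken with the same
microscope, magnification, and pipeline configuration. For this reason
the package always derives coefficients from data and never hard-codes a
published line.

## Transformation chain

Stages, in order, with the `PipelineConfig` defaults:

1. **Grayscale** — Rec. 601 luma (0.299, 0.587, 0.114), round-half-up;
   weights chosen for bit-stable masks across platforms and exposed in
   `miiquant.io.LUMA_WEIGHTS`.
2. **Primary threshold** — level 154, dark-on-bright, boundary
   inclusive (`<= level` is foreground). Produces a provisional mycelium
   mask while the illumination field is still intact.
3. **Background subtraction** — rolling-ball, radius 50 px (the common
   desktop-tool default). For dark-on-bright input the ball rolls under
   the inverted frame and `background − image` is returned clipped to
   [0, 255]: mycelium becomes bright on a zero background. On smooth
   gradients this agrees with a flat-disk grayscale opening to within a
   few gray levels (regression-tested at ≤ 5).
4. **Contrast stretch** — quantile-based linear stretch, 0.35%
   saturation per tail; constant frames pass through.
5. **Secondary threshold** — level 180 on the enhanced bright-on-dark
   signal, ANDed with the *dilated* (3×3 square) primary mask. The gate
   prevents contrast-enhancement artifacts outside the colony from
   entering the mask; dilating first keeps genuine boundary pixels that
   the primary threshold clipped.
6. **Median filter** — radius 1; edge windows are truncated to in-bounds
   pixels rather than reflected, so border medians never count a pixel
   twice.
7. **Speck removal** — connected components (8-connectivity) of the mask
   with area `< min_object_area` (default 20 px) are dropped; a
   component of exactly the floor area is kept. Additionally, components
   smaller than 9 px whose peak intensity stands more than
   `maxima_prominence` (default 10) above the background median are
   dropped as bare impulses even when `min_object_area` is lower. The
   area rule subsumes the impulse rule at the defaults; the impulse rule
   exists so that speck rejection survives a permissive area setting.
   This stage is an interpretation: the workflow it operationalizes was
   described only loosely ("median filters and finding maxima"), so both
   parameters are exposed.
8. **Measurement** — background-zeroed frame, mean over *all* pixels
   (`whole_image` mode). The alternative `mask_only` mode averages over
   mask pixels only; it measures optical density per mycelium pixel
   rather than abundance and is not the default precisely because it
   does not rise with coverage.

The whole chain is deterministic; identical input and configuration give
bit-identical results. Every stage appends its name and parameters to
the result's provenance list, and the CLI writes a manifest with a
config hash that is stable under key reordering.

Polarity conventions are configurable because thresholding direction was
genuinely open: the package assumes bright-field (dark mycelium), under
which level 154 selects `<=` and, after the subtraction inverts the
signal, level 180 selects `>=`.

## Calibration statistics

Ordinary least squares via the closed-form normal equations; standard
errors from the residual mean square; `t = coef/SE` with two-sided
p-values on n−2 df; `F = MS_regression / MS_residual` on (1, n−2) df;
standardized coefficient `β_std = β₁·sd(MII)/sd(DCW)`, which in simple
regression equals Pearson r, so `β_std² = R²` and `t_slope² = F` hold as
identities (tested to 1e−9 relative, and cross-checked against an
independent OLS implementation on random datasets). 95% CIs use the
exact t quantile. Degenerate designs (all MII equal) are rejected rather
than pseudo-inverted: a calibration without intensity spread is
meaningless. No multiple-testing correction is applied; the method
performs single-model inference.

**Degree of accuracy.** Agreement between a predicted and a measured DCW
is reported as `100·min/max`. This statistic is symmetric, bounded by
100, and reproduces both recoverable published worked-example pairs
(270.1 vs 240.5 → 89.0%; 383.9 vs 409.9 → 93.7%), which a
fixed-denominator relative error does not. It is the package's one
deliberate operationalization of an informally described quantity.

**Dilution analysis** fits a separate line per dilution group (several
factors may pool into one label) and reports per-group R². Groups with
fewer than three samples are reported as undefined rather than raising.

## Synthetic data

The generator exists because no real micrograph/DCW corpus is bundled;
it renders what the pipeline must be robust to, with ground truth
recorded before any degradation:

- **Hyphae**: correlated random walks (Gaussian turning angles, sd
  0.3 rad, step 2.5 px) with per-step branching (default probability
  0.15, branches inherit 60% of remaining length), thickness ~3 px.
- **Spores**: ellipses with 3–5 px semi-axes. **Pellets**: a core disk
  (default radius 12 px) with satellite disks around the rim.
- **Background**: level 200 with a ±15 gray-level linear illumination
  ramp; objects at level 60 with per-object jitter (sd 5); additive
  Gaussian noise (sd 5) and dark impulse specks — chosen specifically to
  exercise the background-subtraction, median-filter and speck-removal
  stages.

Morphology parameters are plausible round numbers, not measurements of
any instrument. True object pixel area stands in for biomass; the
MII–DCW link in synthetic calibration tables is linear by construction
(intercept 70.095 mg/L, slope 5.982 mg/L per unit, residual sd 22 —
coefficients and an R²≈0.94 regime representative of a real fermentation
calibration). Each generator draws from seeded sub-streams per object
class, so adding pellets to a spec does not move the hyphae.

**Growth series** shift composition from spore-dominated to
hypha-dominated to pellet-containing stages and enforce non-decreasing
true biomass (stages that would regress are densified), mirroring
monotone growth.

**Dilution experiment.** One field of view of a 1/f-diluted aliquot is
rendered with Poisson-thinned object counts (an undiluted aliquot keeps
its counts deterministically — dilution itself is the sampling process);
the measured MII is the rendered object density, linearized for overlap
via `−ln(1 − coverage)` (the Boolean-model correction for overlapping
grains), rescaled by f, plus Gaussian read noise (sd 2). The true DCW
follows the bulk culture, not the imaged field. Rescaling a sparse field
by f amplifies field-sampling noise like `f/√count`, so per-group R²
degrades mechanically with the factor — the phenomenon the dilution
analysis quantifies. Defaults (600 undiluted-equivalent objects in a
96×96 field, 100 replicates per factor over a 0.6–1.6× biomass ramp)
give a pooled 2–5× group near R² ≈ 0.9 with strictly decreasing groups
at 10×, 100×, 1000×. At 1000× the field is almost always empty — which
is the realistic reason such dilutions are unusable for calibration.

**What passing synthetic tests does not show.** The scenes have crisp
object edges (no point-spread function or defocus), no mycelium-like
debris, and exactly linear illumination; real micrographs will yield
lower segmentation F1 and noisier calibrations than the
regression-tested thresholds (F1 ≥ 0.8, Spearman ρ ≥ 0.9 on a 20-scene
density ramp). The synthetic results validate the machinery and its
statistics, not any particular instrument's accuracy.

## Numerical choices and problem sizes

- All gray-level rounding is round-half-up (`floor(x + 0.5)`), avoiding
  platform-dependent banker's rounding.
- Mask connectivity is 8-neighbor; coordinates are row-major, origin
  top-left, 0-based.
- Thresholds are boundary-inclusive in both polarities.
- Test and acceptance problem sizes: 16×16 frames for brute-force
  operator oracles (100 seeds), 128–256 px scenes for pipeline-level
  checks, 20-scene ramps for monotonicity, 500 replicates at n = 30 for
  CI coverage, 10 generator seeds for the dilution ordering. These sizes
  give stable statistics while keeping the full suite and the acceptance
  script fast on a single CPU.

## Known limitations

- The MII is resolution-dependent; no µm-per-pixel conversion exists.
- Whole-frame measurement assumes the frame is representative; region-of
  interest selection is out of scope.
- No pellet/hyphae morphological classification, fractal analysis,
  z-stacks, or proprietary microscope formats.
- The speck-removal stage is an interpretation of a loosely described
  manual workflow and may differ from the original in edge cases.
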