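# Methods

This note records the models, defaults and design choices behind
`follimech`, in the spirit of a statistical/methods appendix. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Pressure sensing

**Model.** An oil-loaded micropipette connected to a pressure chamber
holds an oil–media interface that is, at the tip scale (< 10 μm
opening), a spherical cap. At mechanical equilibrium the Young–Laplace
relation gives `Pg − 2γ/R = P_far`, where `Pg` is the chamber gauge
pressure, `R` the interface radius of curvature, γ the oil–media
surface tension, and `P_far` the pressure of the phase on the far side
of the interface (0 in open medium; the cavity pressure once inserted).
Differencing the before/after-insertion states,

```
P = (Pg_in − Pg_out) − 2γ (1/R_in − 1/R_out)      [Pa; reported in mmHg, 1 mmHg = 133.322 Pa]
```

Any constant transducer offset cancels in the difference. Hydrostatic
and pipette-resistance corrections are neglected — at tens of μm of tip
depth they are sub-pascal, far below the measured signals.

**Calibration.** The protocol plots gauge pressure against the imaged
interface radius and takes "the slope" as the surface tension. A slope
of pressure against radius does not carry the units of a tension, so
the regression is performed against the curvature `2/R` (Pa per 1/m),
whose slope is γ in N/m and whose intercept is the chamber offset. The
spherical-cap factor 2 is a `cap_factor` argument so a cylindrical
interface convention (factor 1) remains selectable. Fits with
non-positive slope are flagged invalid rather than silently used.

**Circle fitting.** Interface radii come from a geometric (radial
residual) least-squares circle fit, initialized by the Kåsa algebraic
fit and refined with Levenberg–Marquardt. On images, edge points are
the longest mid-level isocontour (subpixel, linear interpolation) with
vertices within 2 px of the frame border discarded, leaving the free
meniscus arc. A direct `(N, 2)` point-array input bypasses edge
extraction for testing. Collinear inputs raise a degenerate-fit error.

## Time-lapse morphometry

Frames are background-subtracted using the median of the two-pixel
border ring (the follicle never touches the frame edge; a full-image
median fails once the follicle covers more than half the field),
thresholded by Otsu (a fixed threshold is available — the original
manual per-image adjustment is deliberately replaced by a reproducible
rule), and the projected area is the pixel count of the largest
connected component times the pixel area.

The expansion model is logistic,
`A(t) = A0 + (Amax − A0)/(1 + exp(−k (t − t50)))`. Fitting is
non-linear least squares with multi-start initialization over rates
{0.4, 1.0, 2.5} h⁻¹ and three inflection guesses; non-convergence
returns a flagged result with diagnostics rather than raising. The
peak-velocity time of the logistic is `t50`; the peak-area time is the
first time the fitted curve reaches 99 % of `Amax` (closed form), a
noise-robust alternative to the argmax of the raw series. When a
rupture is called the fit window ends at the rupture time.

**Rupture call.** A follicle is called ruptured when its area falls
below `(1 − δ)` times the running maximum for at least `m` consecutive
frames (defaults δ = 0.10, m = 3; both configurable). The original
assessment was visual; this criterion is the package's operational
definition and is validated against an exhaustive window-scan oracle.

## OCT morphometry

**Segmentation.** Volumes are Gaussian-smoothed (σ = 1 voxel, a
standard speckle-reduction step; disable with `smooth_sigma=0`) and
split into three intensity classes (three-class Otsu). The Otsu cuts
are then refined to midpoints between class means so each boundary sits
at the half-level of its transition — an off-centre cut would
systematically erode or dilate the wall. The wall is the largest
connected bright component; the antrum is the enclosed region below the
fluid→wall half-level; the COC is the largest intermediate-intensity
component in the cavity that does not touch the (2-voxel-dilated) wall,
automating the original manual identification "separated from the wall,
reduced intensity". Manual thresholds can be passed explicitly.

**Relative antrum volume** is voxel-count antrum / wall (dimensionless;
COC voxels count toward neither compartment).

**Midplane.** The cross-section is the axial slice through the wall
centroid (a fixed index is available). The protocol describes the slice
as the follicle's transverse/vertical midpoint; the centroid slice is
the translation-invariant operationalization. The follicle radius is
the equivalent-area radius `sqrt(area/π)` of the region enclosed by the
outer wall boundary.

**Local thickness** follows the largest-inscribed-disk definition: the
thickness at pixel p is the diameter of the largest disk fully inside
the wall mask that contains p. It is computed by distance-transform +
disk propagation: each mask pixel c carries a disk of radius `EDT(c)`
and every pixel takes the largest diameter over covering disks. Because
the Euclidean distance transform measures to the nearest background
pixel *centre* — half a pixel beyond the boundary on each side — the
reported diameter is `2·EDT − 1` pixels. The implementation is tested
for exact agreement with an all-pairs brute-force oracle.

**Thickness distribution.** Histogram weights are pixel-count fractions
summing to 1 (default bin width 5 μm). The quoted thickness means are
in absolute μm, so normalization applies to the frequency axis, not the
thickness values. The weighted mean is computed from raw pixel values
and is therefore independent of binning. Pixel-count weighting (rather
than arc-length weighting) is used; on an annulus it weights an angular
sector by its local width, which is what "a weighted average of local
thickness measurements" computes in practice.

## Wall stress

Thin-wall Laplace stress `σ = P·r/(2t̄)` exactly as printed in the
source protocol, with the cohort-mean pressure of the (group,
timepoint) cell, the follicle's own outer equivalent radius and its
weighted-mean thickness. No thick-wall (Lamé) correction is applied
even though t/r ≈ 0.2–0.35 is not small — fidelity to the published
estimator is preferred over mechanical refinement, and the quantity
should be read as an index, not an absolute tissue stress. Stress is
reported in Pa with a mmHg column for traceability.

## Cohort statistics

Non-rupturing control follicles are flagged excluded (`no_rupture`);
4-MU-treated follicles are never excluded by that rule (failure to
rupture is the treatment effect). Rows are never deleted, only flagged.
Correlations are simple per-timepoint linear regressions. Group
contrasts are fixed-effects one- or two-way ANOVA with Tukey-HSD
pairwise comparisons at α = 0.05 and a compact letter display (groups
sharing a letter do not differ; insert-and-absorb with alphabetical
tie-break). Rupture rates are percent per replicate with
across-replicate SEM, matching how incidence is reported per culture
replicate.

## Synthetic phantoms

The generators define the study conditions; their defaults are the
anchored cohort values where published, and a single documented choice
elsewhere.

| quantity | default | provenance |
|---|---|---|
| young 0 h pressure | 1.36 ± 0.66 mmHg | published cohort value |
| old 0 h pressure | 2.88 ± 2.36 mmHg | published cohort value |
| young 4–11 h pressure | 3.0 ± 1.0 mmHg | not printed; chosen to satisfy "rises 0→4 h, stays elevated" |
| old 4–11 h pressure | flat at 0 h value | "no significant increase" |
| 4-MU arms pressure | flat at the 0 h baseline | "blocked the normal increase" |
| wall thickness 0/4/8/11 h | 63.1/65.6/50.9/44.4 μm | published cohort values |
| rupture probability | 0.80 control, 0.40 at 0.5 mM, 0.03 at 1 mM | 80 %/3 % published; 0.5 mM interpolated (dose-dependence without a printed value) |
| follicle radius 0/4/8/11 h | 180/200/230/250 μm | not printed; antral-stage scale (diameter ≥ 400 μm) with monotone expansion |
| expansion curve (young control) | A0 1.0e5 μm², Amax 2.0e5 μm², k 1.2 h⁻¹, t50 6 h | chosen so peak velocity falls in 4–8 h and peak area in 8–11 h |
| thickness asymmetry | a = 0.3 | qualitative: wall retains asymmetric thick regions at all timepoints |
| pixel sizes | 2 μm/px (interface), 4 μm/px (time-lapse), 3 μm/voxel (OCT) | desk-scale grids; coarser than instrument resolution |

Per-follicle variability: pressure drawn from the preset normal;
radius and thickness with 5 % CV; expansion parameters with 5–10 % CV
and t50 ± 0.5 h. Rupture times are drawn uniformly 1–5 h after the
inflection, after which the area decays exponentially (time constant
1.5 h) toward 55 % of the pre-rupture value.

Noise models: brightfield area noise is additive Gaussian (default
sd 2×10³ μm²), applied at the series level and propagated into rendered
disk radii; interface-snapshot noise is additive Gaussian intensity
noise calibrated so the implied edge-localization error equals
`noise_sd` pixels (default 0.5 px) — uncorrelated localization noise,
the dominant error of subpixel contour extraction; OCT speckle is
multiplicative gamma noise with 16 looks (CV = 0.25), the standard
fully-developed-speckle approximation after frame averaging.

The OCT shell has azimuthal thickness `t(φ) = c·t̄·(1 + a·cos(φ − φ0))`
with c solved (Brent) so the pixel-count-weighted midplane mean equals
the preset thickness — pixel-count weighting up-weights thick sectors,
so c < 1 for a > 0. The preset `antrum_ratio_mean` is the value
analytically implied by the preset radius and thickness (shell geometry
over-determines it); it is informational, not a fitted target.

Time-lapse phantoms support `render=False`, producing the noisy
measured-area series without rasterizing frames. Rupture-rate and
curve-fit cohort studies (including the acceptance script) use this
series-level mode — the detector and fitter consume area series, and
rendering adds only a verified <2 % area error — while the image →
segmentation → series round trip is exercised on rendered stacks in the
unit tests.

**What the phantoms do not emulate:** out-of-plane follicle drift and
focus changes, non-spherical wall geometry beyond the single cosine
mode, stromal/vascular context, COC expansion over time, OCT
attenuation with depth, shadowing and registration artefacts, and any
biological coupling between pressure, geometry and rupture (each is
drawn independently from its preset). Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated
image-formation models, not robustness to every artefact of real
recordings.

## Problem sizes and numerics

Cohort studies in the tests and acceptance script use 20 follicles ×
10 seeds (pressure), 10 phantoms × 5 seeds per timepoint (OCT at
3 μm/voxel, ~130³–180³ voxel grids), and 100 series × 10 seeds
(rupture), sizes at which the Monte-Carlo standard error is comfortably
inside each recovery tolerance. All randomness flows through
`numpy.random.Generator` seeded per follicle via `SeedSequence.spawn`,
so cohorts are reproducible bit for bit. Degenerate inputs (collinear
arcs, empty masks, open annuli, missing phases, empty design cells)
raise typed errors or set per-record flags; cohort runners flag and
keep failed records rather than dropping them.

Known limitations: the thin-wall stress index above; the logistic
cannot represent the early-peaking, contracting expansion of aged
follicles late in recording (fits there should be read with the rupture
window applied); Otsu segmentation assumes bimodal frames and will
mis-segment empty or saturated fields (flagged as empty); the local
thickness map is exact only up to the one-pixel EDT boundary convention
stated above.
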