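# Methods

This note documents the models, defaults and design choices behind
`dgemric`, and what the synthetic validation does and does not establish.

## Phantom model

Each simulated "subject-compartment" is a single 2D sagittal slice through
the central femoral condyle: subchondral bone is a circle of radius
`condyle_radius_mm` (default 20 mm), cartilage an annular arc of
per-segment radial thickness on top of it, spanning `arc_span_deg`
(default 150°).  The lower half of the arc is the weight-bearing (WB)
segment, the upper half non-weight-bearing (NWB).  Per-segment thickness is
exact by construction, which makes the phantom an analytic oracle for the
thickness and depth machinery.  The slice is 2D because the acquisition
this emulates used independent single sagittal slices per compartment;
nothing in the analysis couples slices.

Tissue ground truth on the mask:

* **Pre-contrast T1** is linear in normalized depth `d` (0 at the
  articular surface, 1 at the bone interface) between a superficial and a
  deep value.  The published data give only two layer values per segment;
  a linear profile is the minimal interpolant between them.  The
  superficial and deep endpoint values default to the published layer
  statistics (e.g. exercise WB 1141/627 ms).  Note the consequence: the
  *measured* layer-ROI means of a linear profile lie between the
  endpoints, so recovery is always asserted against the ground-truth map
  averaged over the same ROI, never against the endpoint number.
* **Gadolinium** follows a diffusion-from-the-surface profile
  `gd(d) = A · erfc(d · thickness / diffusion_depth_mm)`.  The erfc shape
  is the semi-infinite-medium diffusion solution, consistent with contrast
  entering cartilage from the articular surface rather than through bone.
  `diffusion_depth_mm` (default 1.2 mm) sets how far contrast has
  penetrated at the nominal ~2 h imaging delay; it is the knob that makes
  deep-layer concentration thickness-dependent, which is the confound the
  analysis is designed to expose.  The amplitude `A` is calibrated in
  closed form (the erfc integral has an analytic antiderivative) so that
  the mean over the *analyzed* superficial band — normalized depth from
  `guard/thickness` to 1/3, with a half-pixel surface guard by default —
  equals `gd_superficial_mM`.  Calibrating over the full [0, 1/3] band
  instead would make the measured superficial mean undershoot its target
  by ~15%, because the ROI extraction deliberately discards the
  highest-concentration half-pixel at the surface.
* **Post-contrast T1** follows the relaxivity relation
  `1/T1_post = 1/T1_pre + r1·[Gd]` with r1 = 4.1 s⁻¹mM⁻¹.

## Signal simulation

Magnitude inversion-recovery turbo-spin-echo images are simulated per
pixel as `scale · |1 − 2·exp(−TI/T1) + exp(−TR/T1)|` at the protocol's
six inversion times (50–1600 ms) and TR = 2000 ms, pixel size 0.47 mm.
Echo-time and turbo-factor effects are constant across inversion times and
are absorbed into the per-pixel scale, which cancels in T1 estimation.
Noise is Rician: independent Gaussian noise of standard deviation
`noise_sigma · scale` on two quadrature channels, then the magnitude.  The
source protocol does not report SNR; the default `noise_sigma = 0.02`
(SNR 50 at equilibrium signal) is a typical 1.5 T knee-coil figure and is
configurable, not claimed as faithful.  B1/flip-angle imperfections,
motion and pre/post misregistration are out of scope; registration is
assumed exact.

## Cohort priors

Groups are sampled from per-group priors whose defaults are the published
group statistics: normal priors for per-segment thickness (medial/lateral
× WB/NWB), layer T1 and superficial [Gd] (means and SDs of the source
tables), uniform BMI over each group's published range, group sizes 8
(exercise) and 9 (sedentary).  Out-of-range draws (thickness outside the
geometrically valid (0.5, 5) mm, negative values, superficial T1 below
deep T1) are redrawn rather than clipped, to avoid probability mass
accumulating at the bounds; redraws are logged.  Each subject gets an
independent child seed from the cohort seed, so cohorts are reproducible
and subjects independent.

Because the layer-T1 and [Gd] priors are not split by compartment in the
source tables, the two compartments of a subject are independent draws
from the same tissue priors.

## T1 fitting

Magnitude data lose the sign of samples before the null point, so the fit
searches exhaustively over all polarity splits k (negate the first k
samples, ≤ 7 candidates for 6 inversion times) — more robust than sign
fitting at 5–6 points.  For fixed T1 the optimal non-negative scale is the
closed-form linear least-squares solution, leaving a 1D problem in T1:
60 log-spaced grid points on the fit bounds (default 100–3000 ms)
followed by iterative bracketing refinement around the best node to a
10⁻³ ms interval; the best (k, T1) pair over all splits wins.  The
refinement is vectorized over voxels, so map fitting is array-shaped
rather than per-voxel Python.

The finite-TR recovery term `exp(−TR/T1)` is kept: at TR = 2000 ms and
superficial T1 > 1000 ms, dropping it biases T1 by roughly 10%.  The
objective is least squares on magnitude, not a Rician likelihood; the
polarity mechanism absorbs the dominant magnitude effect, and the residual
Rician floor bias is below 1% at SNR 50 (verified by Monte Carlo in the
test suite).  Voxels whose optimum pins at a bound, and all-zero voxels,
are flagged unconverged.  Because the longest inversion time (1600 ms) is
short relative to superficial T1, fitted-T1 variance at T1 ≈ 1100 ms
exceeds that at T1 ≈ 450 ms at equal SNR — a protocol limitation that is
asserted as a property test rather than corrected.

## Depth, layers, thickness

Normalized depth is `d = dist_surface / (dist_surface + dist_bone)` with
Euclidean point-to-polyline distances in mm (pixel-center convention,
0-based indices, mm = pixel × 0.47 by default).  Layers are depth thirds —
superficial `d ≤ 1/3`, deep `d ≥ 2/3`, `layer_fraction` configurable —
with a partial-volume guard of `guard_px` (default 0.5) pixels from either
interface applied to the laminar ROIs only.  Very thin cartilage can leave
a laminar ROI empty after the guard; this returns an explicit empty ROI
with a warning and propagates as a flagged missing value, never a silent
NaN.  Segment splitting uses the phantom's ground-truth labels (standing
in for the study's manual slice placement); an angular-threshold splitter
is provided for external masks.

Thickness is measured at fixed arc-length fractions {0.25, 0.5, 0.75} of
the segment's surface polyline: the inward normal is cast and intersected
with the bone-interface polyline (sub-pixel, via exact segment
intersection), and the three samples are averaged.  Fixed fractions remove
observer dependence of the "three measurements per segment" procedure.

## Quantification

`[Gd]` is computed pixelwise and then ROI-averaged (1/T1 is nonlinear, so
this is the faithful per-voxel reading); the ROI-mean-first variant is
reported alongside as a diagnostic and agrees within 5% under mild T1
heterogeneity.  Small negative concentrations from noise are kept so ROI
means stay unbiased, flagged below −0.05 mM.  BMI correction
(`+3·(BMI−20)` ms, normalizing to BMI 20) is applied to dGEMRIC indices
(bulk post-contrast T1) only — never inside the concentration formula,
which uses measured T1s.

## Statistics

Mann-Whitney between groups, Wilcoxon signed-rank for paired
within-subject contrasts, Spearman for correlations; all two-sided, 0.05
significance.  At the study's sample sizes exact p-values are attainable
and are the default: exact Mann-Whitney for pooled n ≤ 20 without ties,
exact Wilcoxon (2ⁿ sign patterns) for n ≤ 15 non-zero untied differences,
exact-permutation Spearman for n ≤ 8; tie-corrected normal / t
approximations otherwise, and the two modes agree within 0.02 at n = 8
vs 9.  Zero paired differences are dropped (count logged).  The
computations delegate to scipy.stats; the test suite cross-checks the
exact modes against brute-force enumeration written from the definitions.
No multiple-testing correction is applied, mirroring common practice in
small imaging cohorts — with several table cells tested at 0.05, some
nominally significant group contrasts are expected by chance; treat
per-cell p-values descriptively.

The superficial-vs-deep paired contrast is computed per compartment by
default (whether the source pooled compartments is ambiguous); a pooled
option averages compartments per subject first.

## What the synthetic validation shows — and does not

Passing recovery tests show that the measurement chain is unbiased and
precise *under the phantom's assumptions*: exact geometry, linear T1
profile, erfc contrast profile, Rician noise, perfect registration and
segmentation.  They do not validate the chain against real tissue
heterogeneity, segmentation error, partial-volume mixing at curved
interfaces in 3D, or B1 effects.  The confound reproduction (bulk index
and deep [Gd] thickness-dependent, superficial [Gd] independent) holds on
homogeneous-tissue cohorts with varying thickness; in heterogeneous
cohorts the superficial correlation can be non-zero through between-group
structure, which is precisely why the sub-regional reading is preferable
to the bulk index.

## Problem sizes and numerical defaults

Default phantoms are 128 × 128 pixels at 0.47 mm (the condyle arc occupies
~600 mask pixels), cohorts 8 + 9 subjects × 2 compartments; a full
replication (simulation, 68 map fits, tables) runs in a few seconds on one
CPU.  The acceptance suite uses the same sizes, with 2000 replicates for
rank-test calibration and 15 subjects × 2 segments for the confound
analysis.  Fit bounds 100–3000 ms, grid 60 points, refinement tolerance
10⁻³ ms; degenerate inputs (empty masks, all-zero voxels, coincident
interfaces, all-zero paired differences, constant correlation inputs) all
have explicit, tested behaviours.
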