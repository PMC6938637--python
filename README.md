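# dgemric — sub-regional dGEMRIC cartilage analysis

`dgemric` is a Python toolbox for **delayed Gadolinium-Enhanced MRI of
Cartilage (dGEMRIC)** analysis of the knee, with an emphasis on the two
confounders that bias the classical "bulk" reading of the method:
depth-dependent pre-contrast T1 and cartilage thickness.

dGEMRIC estimates relative glycosaminoglycan (GAG) content from the
post-contrast longitudinal relaxation time T1 of cartilage after an anionic
contrast agent (Gd-DTPA²⁻) has distributed inversely to the fixed charge
density.  The usual biomarker — the *dGEMRIC index*, the mean post-contrast
T1 over a full-thickness region of interest — mixes three things: GAG
content, the native (pre-contrast) T1 profile, and how far the contrast has
diffused from the articular surface at imaging time, which depends on
cartilage thickness.  This package implements the sub-regional analysis
that separates them, and a digital-phantom simulator to validate every step
against known ground truth.

## What it computes

For each cartilage segment (weight-bearing WB / non-weight-bearing NWB,
medial and lateral femoral condyle):

* **Voxelwise T1 maps** from magnitude inversion-recovery series, using the
  finite-TR signal model `S(TI) = scale·|1 − 2e^(−TI/T1) + e^(−TR/T1)|`
  with exhaustive polarity-split restoration and a grid-then-refine
  one-dimensional least-squares search
  (`InversionRecoveryT1(series, mask).fit()`).
* **Depth-resolved ROIs**: a normalized depth coordinate
  `d = dist_surface / (dist_surface + dist_bone)` from the interface
  polylines; superficial (`d ≤ 1/3`) and deep (`d ≥ 2/3`) layers with a
  half-pixel partial-volume guard.
* **Thickness** by casting the inward surface normal at arc-length
  fractions {0.25, 0.5, 0.75} of each segment and averaging the three
  sub-pixel intersection distances.
* **Gadolinium concentration** `[Gd] = (1/T1_Gd − 1/T1_pre)/r1` with
  r1 = 4.1 s⁻¹mM⁻¹ (Gd-DTPA²⁻ in plasma at 37 °C), computed pixelwise and
  ROI-averaged.
* **BMI-corrected dGEMRIC indices**
  `T1_corrected = T1_measured + 3·(BMI − 20)` ms.
* **Cohort statistics**: exact small-sample Mann-Whitney (between groups),
  Wilcoxon signed-rank (paired within-subject contrasts) and Spearman rank
  correlations for the thickness-confounding analysis.

Because no public image data exist for this design, the package ships a
first-class phantom generator (`dgemric.phantom`): annular-arc condyle
slices with linear-in-depth pre-contrast T1, an erfc diffusion-from-surface
[Gd] profile, finite-TR inversion-recovery signal simulation with Rician
noise, and two-group cohort priors that reproduce the published thickness,
layer-T1 and superficial-[Gd] statistics of a sedentary group (n=9) and an
exercising elite-runner group (n=8).  Real pre/post T1 maps and ROI masks
in NIfTI form can enter the chain at `fit-t1` / `quantify`.

## Worked example

One command simulates the default two-group cohort (8 exercising + 9
sedentary subjects, medial + lateral condyles, SNR 50) and runs the whole
chain — T1 fitting, layer ROIs, thickness, [Gd], tables, correlations:

```bash
dgemric replicate --out replication_out --seed 42
```

Thickness table (mm, mean ± SD per group with the exact rank-sum p):

```
segment compartment  exercise_mean  exercise_sd  sedentary_mean  sedentary_sd  p_between_groups
     WB     lateral       2.905837     0.149926        2.411671      0.280994          0.000165
     WB      medial       3.015151     0.369322        1.600718      0.634052          0.000165
    NWB     lateral       1.746478     0.262445        1.640148      0.436384          0.962567
    NWB      medial       1.718802     0.151846        1.562928      0.155142          0.035952
```

The medial cartilage comes out thicker in the exercising group, as built
into the priors.  The paired superficial-vs-deep pre-contrast T1 contrast
is significant in every group and segment (exact Wilcoxon p = 0.0078 =
2/2⁸ for all 8 subjects concordant), and the thickness-confounding
correlations pooled over all segments read:

```
rho_thickness_index: rho=+0.852 p=0.0000 (n=68)
rho_thickness_gd_superficial: rho=-0.440 p=0.0002 (n=66)
rho_thickness_gd_deep: rho=-0.973 p=0.0000 (n=67)
```

Thicker cartilage retains an unenhanced deep zone at imaging time, so the
bulk index rises and the deep-layer concentration falls with thickness.
(In this heterogeneous cohort the superficial correlation picks up the
between-group association of thickness and [Gd]; on a homogeneous-tissue
cohort with varying thickness — see the test suite — the superficial
concentration is independent of thickness, which is the diagnostic point
of the sub-regional analysis.)

Library use follows the model/results convention:

```python
from dgemric import AcquisitionSpec, PhantomSpec, InversionRecoveryT1
from dgemric.phantom import build_condyle_geometry, assign_t1_and_gd_fields, \
    simulate_ir_series

spec = PhantomSpec(thickness_by_segment={"WB": 2.9, "NWB": 1.8})
truth = assign_t1_and_gd_fields(build_condyle_geometry(spec))
series = simulate_ir_series(truth.t1pre_map_ms, AcquisitionSpec(seed=1))
results = InversionRecoveryT1(series, truth.mask).fit()
print(results.summary())
```

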