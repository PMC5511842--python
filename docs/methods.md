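# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `petacbias`. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Study design emulated

The pipeline emulates a within-subject comparison of attenuation-correction
(AC) methods: each synthetic subject is "scanned" once, and the same
emission data are reconstructed three times with different μ-maps —
segmented transmission (reference arm), Dixon-MR, and bilinear CT. Scanner
hardware differences between real systems (crystal technology, geometry,
vendor reconstruction implementations) are deliberately *not* simulated:
the three arms share one forward model and one reconstruction code, so any
difference between arms is attributable to the AC method alone. This
isolates the mechanism of interest at the cost of one observable
discrepancy with real multi-scanner data: here the CT arm lands *above*
the transmission reference (CT restores the full bone coefficient that the
transmission segmentation truncates to 0.125 cm⁻¹), whereas in a real
two-scanner comparison cross-system scale effects can pull the CT arm
below the reference. The Dixon arm's sign, the cortical-to-deep gradient,
and the ordering |Dixon bias| > |CT bias| are scale-independent and carry
over.

## Head phantom

A 2-D transaxial slice, 128 × 128 pixels at 2 mm, built from strictly
nested ellipses (semi-axes in mm):

| structure | semi-axes | tissue | μ (cm⁻¹) | HU |
|---|---|---|---|---|
| scalp | 115 × 95 | soft | 0.096 | 0 |
| fat ring | 111 × 91 | fat | 0.086 | −100 |
| skull ring | 106 × 86 → 94 × 74 | bone | 0.1746 | 1500 |
| brain | 94 × 74 | gray | 0.096 | 0 |
| white core | 58 × 42 | white | 0.096 | 0 |

The 2-D choice is deliberate: the bias mechanism under study (bone
adjacency) is radial, fully expressible in-plane, and keeps the iterative
reconstruction desk-scale. The skull ring is 12 mm thick — the thick end of
the adult range — placing the phantom in the regime where the bone
attenuation path dominates the soft-tissue class offsets; with a much
thinner skull the Dixon (no-bone) deficit and the Dixon soft-tissue excess
(0.1 vs 0.095 cm⁻¹ over ~20 cm of tissue) would partly cancel and the
comparison would be dominated by second-order effects. True bone μ is tied
to the skull HU through the same 120 kVp bilinear conversion used by the CT
arm, so 1500 HU ↔ 0.1746 cm⁻¹; the segmented-transmission bone class
(0.125 cm⁻¹) consequently underestimates it by 28.4%.

VOIs are defined on the gray shell by distance to bone (Euclidean distance
transform, mm): the cortical VOI is gray matter within 4 mm of the skull,
the deep VOI gray matter at least 20 mm away, and WBGM the whole shell.

Ground-truth kinetics (plausible verapamil-scale values, configurable, not
asserted as measured values): gray K1 = 0.054 mL·cm⁻³·min⁻¹, k2 = 0.077
min⁻¹; white 0.035 / 0.060; scalp soft tissue 0.020 / 0.10; fat
0.005 / 0.05; bone and air zero. Vb = 0.05 in brain, input delay 3 s. All
activities are decay-corrected to injection time; physical ¹¹C decay is not
simulated (decay correction is universal practice).

## Arterial input functions

The parent-plasma bolus follows the standard Feng tri-exponential

    C_p(t) = (A1·(t−τ) − A2 − A3)·e^{λ1(t−τ)} + A2·e^{λ2(t−τ)} + A3·e^{λ3(t−τ)},  t > τ

(continuous, zero at the bolus start τ), sampled at 1 s on 0–40 min.
Defaults: τ = 0.1 min, A = (500, 20, 4) kBq/mL, λ = (−3.0, −0.35, −0.01)
min⁻¹, giving a peak ≈ 70 kBq/mL about 0.33 min after τ and a 40-min tail
≈ 2.7 kBq/mL — scaled so that late gray-matter concentration lands near
SUV ≈ 0.5 for a 364 MBq dose in a 71 kg subject. The parent fraction
decays smoothly from 1 toward 0.6 (time constant 25 min); whole blood is a
dispersed (100 ms time constant), 0.76-scaled copy of total plasma. The
sampling schedule and dispersion of a real arterial line are not
calibrated to any particular study; the curves are a generic, plausible
stand-in.

## Emission model and reconstruction

Forward model: 2-D parallel-beam Radon transform over 180 evenly spaced
angles restricted to the inscribed-circle FOV, with lengths in cm so that
projecting a μ-map yields the dimensionless ∫μ dl. Attenuation enters in
sinogram space: expected data = P(activity)/ACF with ACF = exp(∫μ dl) ≥ 1.
Count noise, when enabled, is Poisson per bin after scaling the sinogram to
a target expected-count total (default 5 × 10⁶ per study arm, split across
frames in proportion to duration × mean activity).

Reconstruction is ordered-subsets MLEM with the attenuation factors of the
*chosen* μ-map inside the system model (A = diag(1/ACF)·R), 2 iterations ×
21 subsets, followed by a 6 mm FWHM Gaussian post-filter; attenuation
inside the model rather than as a sinogram pre-correction because it is the
better-behaved formulation under count noise. Subsets are interleaved angle
sets; sensitivities are precomputed per subset and reused across frames.

Two numerical choices matter:

* **Initialization.** Iterations start from a filtered-backprojection
  estimate of the attenuation-corrected data (clipped at zero, floored at
  1% of its maximum inside the FOV so the multiplicative update can move
  any voxel). A uniform start leaves thin, edge-adjacent structures
  (the 4 mm cortical ribbon) ~3% short of convergence after the protocol's
  2 iterations; from the FBP start the matched-AC control converges to
  ≈ −1% there and noisy-data behaviour is unchanged. `init="uniform"`
  is available.
* **Back-projector.** The adjoint is the unfiltered backprojection
  (`iradon` with no filter); its constant scale factor cancels between the
  EM numerator and the sensitivity, and the residual forward/backprojector
  interpolation mismatch is below the 0.3% level (measured by running the
  matched control to 16 iterations).

### Matched-AC control

The null control reconstructs noise-free data with the *true* μ-map and
compares regional frame means against the ground-truth activity passed
through the same 6 mm post-filter. The resolution-matched reference
mirrors the study logic (resolution effects are common to all arms and
cancel in arm-to-arm comparisons) and keeps the control meaningful for the
one-ribbon-wide cortical VOI, which a comparison against unfiltered truth
would dominate by partial-volume loss. Frames in which the reference
regional value is below 1% of its regional peak are excluded from the
percent scale (relative error against ~0 is meaningless). The control
stays below 3% in every VOI and frame at the native 2 mm resolution; at
4 mm the one-pixel ribbon under-resolves and the control degrades to ≈ 5%,
which is why reconstruction-accuracy tests run at native resolution.

## Attenuation maps

* **Transmission segmentation**: measured μ (truth + Gaussian noise,
  σ = 0.005 cm⁻¹) thresholded at 0.04 and 0.11 cm⁻¹ — midway between the
  class values, which the class-value definition leaves otherwise free —
  into air/soft/bone = 0/0.095/0.125 cm⁻¹.
* **Dixon**: per-tissue water/fat signals with in = W+F, opp = F−W (the
  convention is fixed so that fat = 0.5(in+opp); the opposite sign
  convention would merely relabel the two recovery formulas). The standard
  three-class map honors the vendor fat/water labeling and therefore
  reproduces the tissue-inversion artifact when that labeling is swapped;
  the inversion-proof two-class map recomputes fat and water from in/opp
  directly and assigns 0.0854 (fat) / 0.1 (soft). The 0.0854 two-class fat
  constant and the 0.085 three-class fat constant are kept distinct on
  purpose. Air is assigned below 5% of the in-phase maximum (a two-class
  rule needs an explicit background mask). Inversion detection: fat-assigned
  fraction inside the head mask > 0.5 (strictly; an exact tie is "not
  inverted").
* **CT bilinear** (120 kVp): μ = 9.6×10⁻⁵·(HU+1000) up to 47 HU, then
  5.1×10⁻⁵·(HU+1000) + 4.71×10⁻²; HU below −1000 are clamped with a
  warning.

In the pipeline the Dixon arm applies the detection-then-correction logic a
site would use: build the standard map, test it for inversion, and fall
back to the inversion-proof map only when flagged (3 of 5 default subjects
are generated inverted).

## Kinetic fitting

Frame values are interval averages of the continuous model prediction
(1 s grid, trapezoid quadrature; the convolution against e^{−k2·t} agrees
with the constant-input closed form to < 0.1%). The fit is weighted least
squares with frame-duration weights (longer frames carry more counts; the
exact weighting is a free choice and is configurable). Because the model
is linear in K1 — and in Vb — the only genuinely nonlinear parameter is
k2, so the optimiser profiles K1 (and optionally Vb) in closed form at
each k2 and searches k2 on a 40-point logarithmic grid refined by bounded
Brent iteration; the refinement is never allowed to return a worse
objective than the grid minimum. The input delay is selected over the
discrete grid {1…5} s by lowest weighted residual sum of squares, ties
broken toward the smaller delay; a delay used to *generate* data is
therefore recovered exactly on that grid in the noise-free case. Vb is
fixed at 0.05 by default (fitting it is supported); whether the original
analysis fitted a blood-volume term is unknown, and the default is
documented rather than asserted.

## Group analysis

Per-subject percent differences (test arm vs reference arm) are tabulated
per region × quantity (SUV, K1, k2, VT) × method pair and summarised as
mean ± sample SD. Significance: per-cell one-sample t-tests against zero,
Holm-Šídák-adjusted within each quantity (step-down Šídák via statsmodels;
rejection strictly below α), starred in the text report at adjusted
p < 0.05. A fixed-effects two-way ANOVA (method × region, with
interaction) is run per quantity; only balanced designs are accepted, and
a zero within-cell error sum of squares is flagged as degenerate rather
than reported as an infinite F. The static SUV image averages frames with
overlap-duration weights over the 10–40 min window (the window cuts
through a 3-min frame of the 18-frame schedule, so a frame contributes
exactly the covered duration).

## What the generator does and does not emulate

Emulated: bone-adjacent cortical vs deep VOI geometry, skull invisibility
to MR, Dixon tissue inversion and its in/opp-based correction, bolus-shaped
metabolite-corrected arterial input with delay, frame-schedule quantisation,
count noise, inter-subject variability (kinetic rates and bolus amplitude
log-normal at 10% CV; dose 364 ± 42 MBq; weight 71 ± 14 kg).

Not emulated: 3-D scanner geometry, scatter/randoms/normalisation,
resolution modelling, realistic MR contrast, motion, atlas registration,
cross-vendor reconstruction differences. Consequently, passing tests show
that the *AC-induced* bias chain behaves as designed; they do not certify
absolute agreement with any human dataset, and absolute K1/k2/VT scales
are validated only by internal parameter recovery.

## Problem sizes

Default study: 5 subjects × 3 arms × 18 frames on the 128-grid
(≈ 270 reconstructions, about 70 s on one CPU); the matched control and
the 100-replicate noise study add a few seconds each. Examples and
pipeline unit tests use a 64-grid, short-schedule variant of the same
study, chosen as the smallest size that still exhibits every qualitative
effect.
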