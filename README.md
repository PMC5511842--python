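# petacbias

A synthetic-study pipeline that quantifies how the choice of PET
**attenuation-correction (AC) method** biases reconstructed radiotracer
concentration, SUV and kinetic parameters in quantitative brain PET.

## The problem

Brain PET protocols are migrating from legacy PET-only scanners to hybrid
PET/MR systems, and the two system families correct photon attenuation very
differently:

* **Segmented transmission (Tx)** — a measured transmission scan segmented
  into air / soft tissue / bone with fixed coefficients
  (0 / 0.095 / 0.125 cm⁻¹). The conservative bone value underestimates dense
  skull (true μ ≈ 0.175 cm⁻¹ at 511 keV) by more than 25%.
* **Dixon MR-AC** — fat/water separation of in-phase/opposed-phase MR images
  mapped to fat / soft tissue / air (0.085 / 0.1 / 0 cm⁻¹). Bone gives no MR
  signal and is treated as air; a vendor failure mode ("tissue inversion")
  swaps the fat and water labels.
* **Bilinear CT** — Hounsfield units converted to 511 keV μ with a
  piecewise-linear map (120 kVp coefficients, breakpoint at 47 HU).

Because every AC error propagates multiplicatively into the reconstructed
activity, the AC method biases regional concentration, SUV, and — through
the arterial-input kinetic fit — the transfer-rate constants themselves.
This package reproduces that causal chain end to end on a synthetic head
phantom, where the ground truth is known exactly.

## What it computes

For each synthetic subject the pipeline builds a 2-D head phantom (scalp,
fat, skull, gray and white matter), generates dynamic activity from a
**one-tissue two-rate-constant (1T2K) compartment model**

    dC_t/dt = K1·C_p(t) − k2·C_t(t),   C_pet = (1−V_b)·C_t + V_b·C_wb,
    V_T = K1/k2

driven by a metabolite-corrected arterial input function, simulates
attenuated parallel-beam emission data with the *true* μ-map, reconstructs
each frame by ordered-subsets MLEM using the μ-map of each AC arm
(2 iterations, 21 subsets, 6 mm Gaussian post-filter), extracts VOI
time-activity curves and static 10–40 min SUV, refits the 1T2K model per
arm, and tabulates per-subject relative differences

    %Diff = (X_test − X_reference) / X_reference · 100%

summarised as mean ± SD with Holm-Šídák-adjusted significance and a two-way
(method × region) ANOVA.

Three VOIs expose the bone-distance dependence of the bias: whole
gray matter (WBGM), a cortical ribbon within 4 mm of the skull (SPL analog)
and deep gray matter at least 20 mm from bone (INS analog).

## Worked example

```bash
python examples/03_kinetic_fit.py
```

```
true:   K1=0.0540  k2=0.0770  VT=0.7013  delay=3s
fitted: K1=0.0540  k2=0.0770  VT=0.7013  delay=3s
after x0.8 TAC scale: K1 shift -22.6%, k2 shift -2.2%
5% frame noise:       K1=0.0518  k2=0.0767  VT=0.6760
```

The fit recovers the generating parameters (and the 3 s input delay)
exactly from a noise-free curve. Scaling the TAC by 0.8 — the kind of pure
concentration-scale error a wrong attenuation map produces — is absorbed
almost entirely by K1 (≈ −20%) while k2, which is determined by the curve's
*shape*, barely moves. That is the mechanism by which AC bias reaches the
kinetic parameters.

The full five-subject study (`pb.run_experiment(pb.ExperimentConfig(seed=1))`,
or `petacbias run-all --out study --seed 1`) prints a report whose SUV rows
look like:

```
Relative differences (%) — SUV
  INS    CT:Tx: +12.8 ± 0.7*   DIXON:CT: -26.5 ± 0.4*   DIXON:Tx: -17.1 ± 0.5*
  SPL    CT:Tx: +33.8 ± 1.0*   DIXON:CT: -59.3 ± 0.6*   DIXON:Tx: -45.6 ± 0.6*
  WBGM   CT:Tx: +18.0 ± 0.2*   DIXON:CT: -36.9 ± 0.3*   DIXON:Tx: -25.5 ± 0.4*
```

Reading: the bone-blind Dixon arm underestimates SUV everywhere relative to
the transmission reference, worst in the bone-adjacent cortical VOI (SPL),
mildest in the deep VOI (INS); the CT arm — which restores the full bone
coefficient that the transmission segmentation truncates — lands on the
other side of the reference with a smaller cortical-to-deep gradient. In
this simulation both arms share one scanner, so the CT:Tx offset is purely
the bone-coefficient difference; K1 and V_T inherit the concentration bias
while k2 moves far less.

### Command-line interface

`petacbias` exposes each stage as a subcommand operating on NIfTI/CSV
files: `phantom`, `acmap`, `simulate`, `tac`, `fit`, `report`, `run-all`.
See `petacbias --help`.

## Layout

```
src/petacbias/
  phantom.py    head phantom, Dixon synthesis, input functions, dynamic truth
  acmaps.py     Tx segmentation, Dixon maps + inversion handling, CT bilinear
  emission.py   forward projection, ACFs, OSEM/MLEM, dynamic simulation
  tacs.py       frame schedule, TAC extraction, static averaging, SUV
  kinetics.py   1T2K model and weighted fit with delay search
  stats.py      percent differences, Holm-Šídák, two-way ANOVA
  pipeline.py   N-subject three-arm orchestration and reporting
  cli.py        thin click CLI
docs/methods.md   model, assumptions, numerical choices, limitations
examples/         one narrative script per capability
```
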