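# Methods

## Signal model

The sequence is an inversion-prepped, gradient-spoiled (FISP-style) SSFP
train. Per repetition: RF excitation, readout at TE, relaxation over the
remainder of the TR, then an ideal one-cycle crusher. The flip angle ramps
linearly from 0.778° to 70°; TR and TE are constant (10 ms / 2 ms) and the
train has 500 timepoints by default. TR, TE and the timepoint count are
package configuration — the acquisition this pipeline models does not pin
them at desk scale — and every quantitative result states them through the
run configuration. A single adiabatic inversion (efficiency 1.0, exposed
as a parameter) precedes the train.

Propagation uses the extended-phase-graph (EPG) formalism. With the RF
phase fixed on the y axis and no off-resonance, all configuration states
stay real, so fingerprints are real signed sequences bounded by the
equilibrium magnetization. The crusher is modelled as an instantaneous
end-of-TR shift of the transverse configuration ladder; the recorded echo
is F₀ after the pulse decayed by exp(−TE/T2). Off-resonance, B1 error,
magnetization transfer and diffusion are deliberately outside the model.

**State truncation.** 150 configuration orders are retained. Long-T2 spins
keep high dephasing orders alive across many TRs, and aggressive
truncation is visibly wrong there: against a brute-force isochromat
simulation (2000 spins uniformly dephased over one crusher cycle — exact
for trains shorter than the spin count), 20 retained orders err by 8.7e-2
relative L2 at T1 = T2 = 5000 ms, 100 orders by 2.3e-3, while 150 orders
stay below 5.0e-4 everywhere on [10, 5000]² ms. The isochromat simulator
is kept in the test suite as the independent oracle.

## Dictionary and matching

The (T1, T2) grid concatenates inclusive arithmetic segments whose step
widens with the relaxation time, mirroring the exponential character of
relaxation: T1 `10:5:100, 110:10:1000, 1050:50:2000, 2100:100:3000`
(139 values), T2 `10:1:100, 105:5:500, 525:25:1000, 1100:100:2000`
(201 values), 27,939 pairs in T1-major order. Pairs with T2 > T1 are
physically unusual but retained by default, exactly as the ranges imply;
a T2 ≤ T1 filter is available and off by default.

Atoms are L2-normalized simulated fingerprints. Compression projects them
onto the top-r left singular vectors of the atom matrix (computed from the
timepoint-level Gram matrix; basis signs fixed for determinism). At the
default rank 15 the relative Frobenius reconstruction error of the default
dictionary is ~3.4e-4, and compressed matching reproduces uncompressed
matched pairs on all noiseless on-grid probes.

Matching maximizes |⟨s, d⟩|/‖s‖ over unit atoms; signals are normalized
*after* basis projection (the alternative order is unstated upstream; this
one is documented and tested). Ties break toward the smaller linear atom
index, deterministically. Proton density is the least-squares amplitude of
the matched atom — for a probe that is a scaled clean fingerprint, exactly
that scale times the fingerprint's norm. The 512³ display interpolation of
clinical pipelines exists only as a cosmetic upsampling helper and feeds
no quantitative path.

## Acquisition analog

The clinical chain (3D multi-axis spiral, view sharing, GPU gridding) is
reproduced as a 2D single-coil analog that preserves the algorithmic
structure at desk scale:

* **Trajectory** — one interleaf per timepoint, rotated per frame by the
  golden angle (137.508° spiral / 111.246° radial). The default spiral is
  a single Archimedean arm, 8 turns, 4×matrix samples per frame (at 64²
  this is ~16× undersampling per frame). The sampling density along the
  readout matters: at 2×matrix samples per frame the longest-T2 insert of
  the integration phantom reconstructs one-and-a-half grid steps off,
  while 4×matrix recovers every insert within one step.
* **Forward model** — exact non-uniform DFT of the per-frame signal image
  (PD × fingerprint value), plus complex white Gaussian noise at a stated
  SNR (mean voxel signal magnitude over the object mask / complex noise
  SD per sample).
* **View sharing** — each output frame borrows the samples of its window
  of neighbors. Temporal kernel: Gaussian (σ = window/6) or uniform,
  normalized over the contributing frames. A k-radius blend keeps the
  k-space center native (|k| < 0.1·k_max), shares the periphery fully
  (|k| > 0.3·k_max) and ramps linearly between; weights sum to one per
  sample position, so a static object is averaged, never double-counted.
  The exact weighting of the clinical implementation is not public; this
  scheme is an explicit stand-in with every threshold configurable.
* **Gridding** — per-sample density compensation (|k| ramp for radial and
  spiral, with a floor so DC keeps finite weight; flat for Cartesian),
  Kaiser–Bessel interpolation (width 4, oversampling 2, Beatty β), inverse
  FFT, deapodization by the kernel's FFT-computed transform, and a
  per-frame normalization against the gridded sampling density. The fully
  sampled Cartesian special case reproduces the plain inverse FFT to
  machine precision, which pins the overall calibration.

## Synthetic inputs

**Phantom.** 14 discs on a ring in a 64² matrix, ground-truth T1
log-spaced over 20–1980 ms and T2 over 15–1600 ms, paired by insert index.
The physical reference phantom's certified per-vial values are not public
in the modelled study, so these log-spaced values are an explicit
synthetic stand-in spanning the measured ranges; truth is always carried
alongside the rendered volumes. Sessions scan the phantom 7 times at SNR
30 (noise added voxelwise to the fingerprints by default; the full
acquisition chain is available as a mode), with per-repeat noise streams
derived deterministically from the session seed.

**Cohort.** 20 patients, 25 meningiomas (one patient with three tumors,
three with two), and one record per normal structure per patient. Each
structure's T1 and T2 are independent Gaussians truncated at 1 ms with the
published per-structure means/SDs (meningioma 1429 ± 202 / 69 ± 27 ms;
thalamus 1054 ± 58 / 27 ± 3; caudate head 1223 ± 52 / 39 ± 5; centrum
semiovale 825 ± 42 / 29 ± 5; contralateral white matter 799 ± 45 / 35 ± 4).
Within-patient correlation of the normal structures is zero by default and
exposed as an equicorrelation parameter — the source tables publish only
marginals, so any nonzero value is a modelling choice. What the generator
does *not*
emulate: partial-volume mixing at ROI borders, spatial noise correlation,
B1/B0 field structure, within-patient correlation of structure values, and
real lesion heterogeneity. Passing tests therefore demonstrate the
correctness and calibration of the pipeline under its stated noise model,
not scanner-grade accuracy on real tissue.

## Statistics

Phantom accuracy: OLS of measured on reference (r² = squared Pearson
correlation) and MAPE = mean(|measured − reference| / reference) × 100,
optionally restricted to a reference range (clinical windows: T1
500–2000 ms, T2 15–200 ms). Repeatability: per-vial sample SD (n−1) across
repeats.

In-vivo: one block per meningioma, columns = [meningioma, thalamus,
caudate head, centrum semiovale, contralateral white matter], multi-tumor
patients duplicating their normal-structure values across blocks — the
study's stated pairing, reproduced rather than "corrected", although the
duplicated rows violate strict block independence. Friedman statistic with
mid-ranks and the classical tie correction, p from χ²(k−1); Dunn z =
(R̄ᵢ − R̄ⱼ)/√(k(k+1)/(6n)) with two-sided normal p, Bonferroni-adjusted
over the 10 pairs by default (none/Holm selectable — whether the source
analysis adjusted is unstated, so both are reported). Significance is
fixed at p < 0.05.

Numerical caveats: the χ² tail is a large-n approximation — at 25 blocks
it tracks a 10⁴-resample permutation oracle within Monte-Carlo error, but
for k = 2 at n ≤ 8 it deviates from the exact sign-test enumeration by up
to ~0.25 (no continuity correction), while preserving the p ordering.

## Known limitations

* The statistical power of the marginal contrasts is limited under the
  independent-Gaussian cohort model: the meningioma-vs-CWM T2 and
  meningioma-vs-thalamus T1 Dunn comparisons only clear adjusted p < 0.001
  in a minority-to-moderate fraction of simulated cohorts (the acceptance
  suite computes and documents the rates), consistent with the marginal
  published thalamus-T1 p of 0.001. Real data plausibly benefit from
  within-patient correlation that the marginals cannot encode.
* Single coil, 2D geometry, ideal spoiling and no system imperfections:
  phantom accuracy figures from this pipeline are idealized bounds, better
  than scanner reality.
* Problem sizes (64² matrix, 500 timepoints, 27,939 atoms, 10³–10⁴
  simulation replicates) are the package's reference desk-scale
  configuration; everything is configurable upward.
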