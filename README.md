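# mrfpipe

Desk-scale MR fingerprinting (MRF) relaxometry: fingerprint simulation,
dictionary matching, an undersampled view-shared acquisition analog, and
the phantom/cohort statistics used to validate quantitative T1/T2 mapping
of the brain.

## Who this is for

MRF replaces steady-state MR acquisitions with a train whose flip angle
varies over time, so that every tissue (T1, T2) combination traces a unique
signal evolution — its *fingerprint*. Quantitative maps are decoded by
matching each voxel's measured evolution against a precomputed dictionary
of simulated fingerprints. `mrfpipe` implements that whole chain at
workstation scale for method development, teaching and validation studies:
everything runs in minutes on one CPU, with synthetic but fully
ground-truthed inputs (a NIST-style multi-insert relaxometry phantom and a
meningioma patient cohort), or on real NIfTI T1/T2 maps plus integer ROI
label volumes.

## The model

**Signal model.** An inversion-prepped, gradient-spoiled SSFP train with a
linear flip-angle ramp from 0.778° to 70° (defaults: 500 timepoints,
TR = 10 ms, TE = 2 ms). Voxel magnetization is propagated with the
extended-phase-graph (EPG) formalism — configuration states
F<sub>k</sub><sup>±</sup>, Z<sub>k</sub> under RF mixing, relaxation and a
one-cycle crusher per TR — which a brute-force dephased-isochromat Bloch
simulation reproduces to machine precision.

**Dictionary.** One unit-norm atom d(T1, T2) per pair of a piecewise grid
whose steps widen with the relaxation time (T1 10–3000 ms in segments
`10:5:100, 110:10:1000, 1050:50:2000, 2100:100:3000`; T2 10–2000 ms in
`10:1:100, 105:5:500, 525:25:1000, 1100:100:2000`; 139 × 201 = 27,939
atoms). Atoms are compressed onto the top-15 left singular vectors of the
atom matrix; matching maximizes |⟨s, d⟩| / ‖s‖ over the dictionary and
reports the matched (T1, T2), the correlation, and the least-squares atom
amplitude as a proton-density surrogate.

**Acquisition analog.** A 2D rotating single-interleaf trajectory
(golden-angle spiral or radial), an exact non-uniform DFT forward model,
k-space-weighted view sharing (center native, periphery shared), and
density-compensated Kaiser–Bessel gridding with inverse FFT.

**Validation statistics.** Phantom accuracy by OLS of measured against
reference times (r², MAPE, optionally range-restricted), repeatability as
per-vial SD across repeat scans, and blocked in-vivo comparisons by a
tie-corrected Friedman rank ANOVA with Dunn post-hoc z tests — one block
per tumor, multi-tumor patients re-pairing their normal structures.

## Worked example

```python
import numpy as np
from mrfpipe import (default_schedule, build_grid, build_dictionary,
                     compress, match, simulate_fingerprint)

schedule = default_schedule(500)
dic = compress(build_dictionary(build_grid(), schedule), rank=15)  # ~40 s

probe = simulate_fingerprint(1007.0, 52.0, schedule)   # off-grid tissue
rng = np.random.default_rng(0)
noisy = probe.signal + np.abs(probe.signal).mean() / 30 * rng.standard_normal(500)
m = match(noisy, dic)
print(f"matched T1 = {m.t1_ms:.0f} ms, T2 = {m.t2_ms:.0f} ms, "
      f"correlation = {m.correlation:.4f}")
```

```
matched T1 = 1000 ms, T2 = 52 ms, correlation = 1.0000
```

The off-grid ground truth (1007, 52) lands on the nearest grid entries at
SNR 30 — T1 within one 10 ms grid step, T2 exact.

Cohort statistics reproduce the study's summary-table layout:

```python
from mrfpipe import generate_cohort, table1
tab = table1(generate_cohort(seed=1))
print(tab[["n", "t1_mean_ms", "t1_sd_ms", "t1_p_vs_meningioma"]].round(3))
```

```
                             n  t1_mean_ms  t1_sd_ms  t1_p_vs_meningioma
structure
meningioma                  25    1445.765   199.641                 NaN
thalamus                    20    1061.951    61.230               0.001
caudate_head                20    1219.653    54.436               0.603
centrum_semiovale           20     830.612    35.996               0.000
contralateral_white_matter  20     802.273    54.685               0.000
```

Meningioma T1 separates sharply from white matter (Bonferroni-adjusted
Dunn p < 0.001) while the caudate head does not — the expected pattern for
these distributions.

A command-line driver wraps the same library:

```sh
mrfpipe run-all --config my_config.json   # phantom validation + cohort stats
mrfpipe build-dict --out dict.h5          # 27,939-atom HDF5 dictionary
```

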