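# cmrsi — compartment-based reconstruction of 3D ³¹P cardiac MRSI

`cmrsi` is a toolkit for **compartment-based reconstruction of
acquisition-weighted, phase-encoded ³¹P cardiac MR spectroscopic
imaging**, aimed at spectroscopists who want to study how SLAM-family
reconstructions behave before taking them to a scanner.  Cardiac ³¹P
MRSI is chronically SNR-starved: the phosphocreatine-to-ATP ratio
(PCr/ATP), the standard cardiac energetics biomarker, must be
extracted from minutes-long acquisitions whose Fourier reconstruction
wastes signal on a single small voxel.  Compartment-based methods
instead reconstruct one spectrum per anatomically segmented region
(heart, chest wall, everything else), trading spatial resolution for
SNR and a spatial response function (SRF) that hugs the heart.

The package implements, end to end on a synthetic digital phantom:

* **SLAM** — discretize the MRSI signal equation, `S = PE·ρ`, compress
  the DFT encoding matrix by averaging its columns within each
  compartment, and solve with the Moore–Penrose pseudoinverse `H`.
  Rows carry the per-encode repeat count `R_m`, so summed
  acquisition-weighted (AW) data reconstruct directly.
* **SLIM** — the continuous-FT analogue: `g_mc = R_m ∫_c e^{-i2πk_m·x} dx`
  evaluated in closed form (separable per-axis sinc factors over voxel
  boxes), pseudoinverted the same way.
* **fSLAM** — numerical optimization of the fractional per-axis k-space
  coordinates of a truncated scheme (12 free parameters for a 4×4×4
  block) against an SRF-based cost: out-of-compartment leakage
  `Σ|β(x)|²` plus in-compartment nonuniformity `var β(x)`, optionally
  receive-sensitivity weighted.
* **SRF / PSF analysis** — `β_c(x) = Σ_m h_cm R_m e^{-i2πk_m·x}`, its
  worst-case magnitude and B₁-weighted variants, FT voxel PSFs and
  leakage tables.
* **Forward simulation** — a voxelized three-compartment cardiac
  phantom (spheroidal heart, curved chest-wall slab, background) with
  Lorentzian ³¹P resonances (PCr, γ/α/β-ATP, 2,3-DPG doublet, PDE),
  polynomial B₀/phase maps, Biot–Savart surface-coil sensitivities,
  and per-repeat noise so AW schemes acquire k-dependent noise
  variance.
* **Fitting and metrics** — time-domain damped-exponential fitting with
  analytic Jacobians and CRLBs, PCr SNR, blood (2,3-DPG) and
  steady-state saturation corrections of PCr/ATP, and the test–retest
  coefficients of reproducibility (CoR = 1.96 × SD of paired
  differences) and variation (pooled SD / mean).

## Worked example

Simulate one AW acquisition of a phantom with mild B₀ inhomogeneity,
combine the two surface-coil channels, reconstruct the heart
compartment with SLAM and fit it:

```python
import numpy as np
from cmrsi import *
from cmrsi.pipeline import heart_fit_model

phantom = make_cardiac_phantom(PhantomConfig(b0_peak_hz=20.0, phase_peak_rad=0.2))
mask = CompartmentMask.from_phantom(phantom)
scheme = make_aw_scheme((8, 16, 8), center_averages=4, omit_zero=True)
print(f"AW scheme: {scheme.n_encodes} phase encodes, {scheme.total_readouts()} readouts")

sens = biot_savart_sensitivity(default_cardiac_coil(), phantom.grid)
kdata = forward_encode(phantom, scheme, sensitivity=sens / sens.mean(),
                       noise_sd=45.0, seed=7)
combined = wsvd_combine(kdata, noise_cov=np.eye(2))

op = compress_compartments(build_pe_matrix(scheme, mask.grid), mask, scheme=scheme)
print(f"SLAM operator condition number: {op.condition_number:.2f}")
spectra = slam_reconstruct(combined, op)

fit = fit_time_domain(spectra.compartment(2), heart_fit_model(phantom, 2.0e-4))
print(f"PCr SNR: {compute_snr(fit, 'PCr'):.1f}")
print(f"PCr linewidth: {fit.linewidths_hz['PCr']:.1f} Hz")
print(f"blood+saturation corrected PCr/ATP: {pcr_atp_ratio(fit, CorrectionConfig()):.2f}")
```

Output:

```
AW scheme: 369 phase encodes, 568 readouts
SLAM operator condition number: 3.06
PCr SNR: 26.8
PCr linewidth: 41.7 Hz
blood+saturation corrected PCr/ATP: 2.65
```

The 369 encodes are the hard-thresholded 8×16×8 Hamming-weighted
matrix (outer k-space rounds to zero repeats); the condition number
says the three-compartment system is comfortably invertible; the
PCr/ATP value reflects the phantom's configured heart composition after
blood and saturation corrections (the same corrections applied to all
techniques, so cross-technique comparisons are unaffected by their
configured constants).

A six-technique synthetic test–retest study (AW FT-MRS, AW SLAM, AW
SLIM, 4×4×4 SLAM, 4×4×4 SLIM, fSLAM) is one call —
`run_study(StudyConfig(n_subjects=8), seed=0)` — or from the shell:

```bash
cmrsi study run --seed 0 --out results/study
cmrsi scheme make --kind central --out scheme.csv
cmrsi phantom make --out labels.nii.gz
```

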