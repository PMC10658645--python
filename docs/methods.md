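# Methods

This note records the models, conventions and numerical choices behind
`cmrsi`, and what the synthetic tests do and do not demonstrate about
real data.

## Coordinate and data conventions

All modules share one DFT-consistent convention: along an axis with
`M` voxels, voxel centers sit at FOV-normalized positions
`x̃_j = (j − ⌊M/2⌋)/M`, so integer k-space coordinates are cycles per
FOV; voxels are linearized x-fastest. Phase-encode repeats are stored
**summed**, never averaged: the acquired signal of encode `m` is the
sum of its `R_m` repeats, and `R_m` therefore appears as a row
weighting inside the reconstruction operators rather than as a data
correction. Noise is drawn independently per repeat (circular complex,
complex SD = `noise_sd` per average) and summed, so acquisition
weighting automatically produces the `R_m·σ²` k-dependent noise
variance a scanner would record.

## Forward model

The simulator evaluates the discretized MRSI signal equation on the
phantom grid: for each coil channel and encode,
`s(k_m, t) = R_m Σ_x sens(x)·fid_x(t)·e^{−i2πk_m·x̃}` with
`fid_x(t) = Σ_r a_r ρ(x) B₁(x) e^{i(φ_r+φ(x))} e^{i2π(f_r+Δf(x))t} e^{−π·lw_r·t}`.
The spectral model is a sum of Lorentzian lines; B₀ enters as a
per-voxel frequency offset `Δf(x)` and phase `φ(x)` (smooth fixed
second-order polynomials scaled by configurable peak amplitudes,
default 0 = homogeneous), and the transmit field as a multiplicative
amplitude scale. The optional shaped-pulse excitation profile is a
Gaussian frequency response applied to resonance amplitudes; the
default is flat.

`refine_phantom` subdivides the grid by an odd factor while keeping
the phantom piecewise-constant on the original voxel boxes (labels
assigned by nearest coarse center, with periodic wrap at the FOV edge,
consistent with integer-k DFT encoding). Data simulated on refined
grids converge to the continuous FT of the voxelized object; this is
how the SLIM convergence study avoids the inverse crime of testing a
continuous-basis method only against data discretized on its own grid.

## Reconstruction operators

**SLAM.** The full `M′×N_vox` phase-encode matrix has entries
`R_m e^{−i2πk_m·x̃_j}`. Compartment compression averages columns within
each compartment (per-voxel-mean normalization, as the δ-property and
the matrix identities below require). The pseudoinverse is computed by
SVD with rank tolerance `max(M′,C)·eps·σ_max`; the condition number is
always attached to the operator, and rank deficiency or conditioning
above 1e8 attaches a warning rather than failing. Solving
`H·data` yields the compartment-integrated signal; the default
`per_voxel_mean` output divides by the compartment voxel count so the
reported spectrum sits on the scale of a single voxel spectrum
(directly comparable across compartments and with FT-MRS voxels); the
`total` flag skips that division. With singleton-voxel compartments
and a uniform single-average scheme, SLAM reduces exactly to the
FT-MRS voxel spectrum. Under nonuniform repeats the two differ by
design: SLAM solves an `R²`-weighted least-squares problem while
FT-MRS keeps the repeat pattern as apodization.

**SLIM.** `g_mc = R_m Σ_{j∈c} Π_d w_d·sinc(k_d w_d)·e^{−i2πk_m·x̃_j}`,
the exact integral of the CFT basis over the compartment's voxel boxes
(`w_d` the FOV-normalized voxel width), divided by compartment volume
for comparability with SLAM. Against point-sampled same-grid data this
closed form carries an irreducible CFT-vs-DFT mismatch of a few
percent at 8×16×8; against box-profile (refined-simulation) data it is
exact to machine precision. Both behaviours are asserted in the tests.

**FT-MRS.** Integer-k data are placed on the matrix grid, missing
encodes zero-filled, and inverse-DFT'd per axis with the shifted-basis
matrices matching the center convention. Summed repeats are
transformed as-is (acquisition weighting acts as apodization; no
division by `R_m`). The midseptal voxel used for cardiac readouts is
the caller's choice; the pipeline picks the heart-centroid voxel.

**Coil combination.** Channels are whitened by the inverse Cholesky
factor of the channel noise covariance, stacked, and replaced by the
rank-1 SVD term; the combined FID is the dominant right singular
vector scaled by the dominant singular value and phased to the
dominant channel. The simulation pipeline passes the identity
covariance because simulated channels carry i.i.d. equal-variance
noise; the tail-based estimator is provided for data with a genuinely
signal-free tail but is signal-contaminated for short FIDs, so it is
not used by default.

## Spatial response functions

`β_c(x) = Σ_m h_cm R_m e^{−i2πk_m·x̃}` evaluated on the acquisition
grid or an oversampled copy (evaluated in memory-bounded blocks). The
worst-case contamination map is `|β_c(x)|` (realized when the local
B₀-induced phase opposes the SRF phase) and can be weighted by a
receive-sensitivity map. On the acquisition grid the per-voxel mean of
`β_c` over compartment `d` equals `δ_cd` exactly for SLAM; for SLIM
the same identity holds as a volume integral, checked by midpoint
quadrature on a 9× oversampled grid (quadrature error ~7e-4,
second-order in the cell width). Leakage tables integrate
`|β|` (optionally sensitivity-weighted) over box-consistently
upsampled compartment regions. The FT PSF threshold for voxel contours
defaults to 0.64 and is exposed as a parameter.

## fSLAM optimization

The free parameters are the concatenated per-axis fractional
coordinate vectors of a separable scheme (4+4+4 = 12 for a 4×4×4
block). The cost is this package's formulation of the verbal
leakage/uniformity decomposition:
`w₁·Σ_{x∉target}|β_target(x)|² + w₂·var_{x∈target}(β_target(x))`,
with `β` recomputed from a SLAM operator at each candidate point and
optionally sensitivity-weighted; `w₁ = w₂ = 1` by default. A bounded
Powell search from the integer initial coordinates (±1 cycle/FOV) is
used; repeats, and hence the readout budget, are untouched, and the
initial scheme is returned whenever no strict improvement is found.
The heart is the default target compartment, mirroring per-subject
optimization. Six Powell iterations (the study default) give most of
the attainable cost reduction at ~3 s per subject; the cap is a
configurable accuracy/runtime trade-off of this implementation.

## Spectral fitting, CRLB, corrections

Fitting is bounded nonlinear least squares of
`Σ_r a_r e^{iφ_r} e^{(i2πf_r−π·lw_r)t}` against the stacked
real/imaginary FID samples with analytic Jacobians, multi-started over
deterministic frequency offsets within the prior bounds. Prior
knowledge is per-resonance frequency/linewidth bounds, an optional
shared zeroth-order phase (the default) and a fixed first-order phase
term; ATP moieties are single Lorentzians. CRLBs are
`sqrt(diag((JᵀJ/σ²)⁻¹))` on the stacked Jacobian; parameters with
pinned bounds can be marked fixed and are removed from the Fisher
matrix (the textbook `σ/√N` amplitude bound for an undamped resonance
holds only with the linewidth held known, because amplitude and
damping are Fisher-correlated). The noise SD entering SNR and CRLBs is
the per-component SD of the final quarter of the FID after fit
subtraction; at SNR 15 the Monte-Carlo parameter SDs attain the bounds
within a few percent.

PCr/ATP corrections: γ-ATP minus a configurable fraction (default
0.30, a placeholder — the constant is site-specific and not derivable
here) of the mean 2,3-DPG doublet amplitude, clamped at zero with a
warning; then division of PCr and γ-ATP by the steady-state saturation
factor `E = (1−e^{−TR/T1})sinα/(1−cosα·e^{−TR/T1})` with
per-metabolite T₁ (defaults 3.4 s PCr, 1.8 s γ-ATP) and effective flip
(default 30°). Ratios are invariant to the overall output
normalization of the reconstruction, so these constants shift all
techniques identically.

## Synthetic test–retest study

Eight synthetic "subjects" per run: heart semi-axes uniform in
40–55 mm, center jitter ±10 mm, B₀ peak 10–35 Hz, phase peak
0–0.3 rad; two scans per subject differing only in the noise seed; all
draws descend from one seed. Each scan simulates the three
acquisitions once (AW 8×16×8 Hamming with 4 center averages,
hard-thresholded; central 4×4×4 with 6 averages = 384 readouts; fSLAM
optimized 4×4×4) and feeds them to the matching reconstructions, so
techniques sharing a scheme consume byte-identical data. The
per-average noise SD default of 45 was chosen once so the single-voxel
AW FT-MRS readout lands in the low-teens PCr SNR regime typical of
7 T cardiac ³¹P, and the time grid is 256 points at 5 kHz bandwidth.
Acquisition sizes (8×16×8 over a 240×240×200 mm FOV) match the
protocol the phantom emulates; study sizes (8 subjects, 256 time
points) are the package defaults chosen to keep a full run around two
minutes on one CPU.

What passing tests show: the operators are algebraically correct
(exact recovery, δ-properties, closed-form noise propagation), the
fitter attains its CRLBs, and under matched synthetic conditions the
compartment reconstructions beat the single-voxel readout's SNR while
noiseless test–retest differences vanish. What they do not show:
robustness to motion, realistic B₀/B₁ distributions, partial-volume
and blood-pool segmentation errors, or any in-vivo reproducibility
level — the phantom has no motion, its compartments are internally
homogeneous by construction, and its field maps are smooth low-order
polynomials.

## Known limitations

* The AW window of the emulated protocol is not uniquely determined by
  its published readout total; the Hamming default here yields 568
  readouts (hard-thresholded), not 396, and readout totals are treated
  as order-of-magnitude matched, not exact.
* SLIM's closed-form integrals assume compartments are unions of
  reconstruction-grid voxel boxes; masks finer than the acquisition
  grid are supported only through a finer reconstruction grid.
* The blood/saturation correction constants are configuration, not
  measurements; absolute PCr/ATP values depend on them even though
  technique comparisons do not.
* `estimate_noise_cov` from the FID tail is biased whenever the tail
  retains signal; prefer a supplied covariance (or identity for
  simulated data).
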