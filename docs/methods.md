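# Methods

`cisubquant` simulates and evaluates the quantification chain of subtracted
contrast-enhanced micro-CT: how the choice of reconstruction algorithm
(analytic filtered backprojection vs. iterative SIRT) and edge-preserving
noise removal (a 3D bilateral filter) propagates into the accuracy and
precision of the iodine concentration C_I measured from subtracted images.
Every stage of the chain is implemented and tested against an independent
oracle; a digital phantom simulator stands in for the scanner so the whole
study is reproducible from a single seed.

## Forward model

**Phantoms.** Four standard phantoms mirror the usual micro-CT
quality-assurance set: a uniform water cylinder (noise/NPS), an acrylic
semi-cylinder whose flat face provides a high-contrast straight edge (MTF),
a set of calibrated iodinated cylinders — a water-equivalent body with a
single centred insert at 0, 0.5, 1.0 and 3.0 mg I/ml — and an
"in-vivo-like" body with tumour/vessel/muscle surrogate inserts.  Phantom
diameters and insert sizes are configuration values (defaults: 24 mm body,
8 mm insert), chosen as plausible small-animal-scanner dimensions; they are
deliberately not claims about any physical phantom.  The semi-cylinder's
flat face is tilted 3° in-plane so that the edge-method MTF estimator
receives sub-pixel edge samples, as in standard slanted-edge practice.

**Attenuation.** The forward model is monoenergetic: each material is one
linear attenuation coefficient at the effective energy of a ~45 kVp
spectrum (water 0.0375 mm⁻¹, acrylic 0.044 mm⁻¹, air 0), and iodine adds
k_I = 0.0022 mm⁻¹ per mg I/ml (iodine mass attenuation ≈ 22 cm²/g near
30 keV).  This makes 1 mg I/ml worth ≈ 59 ΔHU, the same order as the
printed calibration slopes of real subtracted micro-CT (≈ 45 ΔHU per
mg I/ml).  Spectral effects (beam hardening, energy weighting) are not
modelled; because the C_I calibration is *fitted* to the simulated
subtracted images rather than assumed, any linear spectral scale factor
would be absorbed exactly as in a physical calibration.

**Projection.** Geometry is 2D parallel-beam applied slice by slice
(cone-beam is out of scope).  Line integrals are computed by Joseph-style
linear-interpolation ray tracing; the operator is materialised as a sparse
matrix per (geometry, grid) pair, so the backprojector used by SIRT is its
exact adjoint by construction (`A.T`), which the test suite verifies to
machine precision.  Counting noise follows the transmission model:
N ~ Poisson(I0·e^(−p)) per bin, converted back to line integrals
−log(N/I0); zero counts are floored at 0.5 counts.  The desk-scale default
is 200 angles and I0 = 1e5 photons/bin; the full protocol value of 400
projections is available via configuration.

Simulation uses its own grid (200², 0.16 mm in-plane), finer than either
reconstruction grid, so that no reconstruction runs on the grid that
generated the data.

## Reconstruction

**FBP** is the textbook per-slice algorithm: frequency-domain ramp filter
(Hann-apodized at full Nyquist cutoff by default — the vendor kernel of
real scanners is unpublished, and the analysis only requires FBP to be the
linear comparator), pixel-driven linear-interpolation backprojection,
scaling π/n_angles.  On a noiseless disk the interior RMSE is < 2% of μ
and the result agrees with an independent inverse-Radon implementation.

**SIRT** iterates x ← x + λ·C·Aᵀ·R·(p − A·x) from a zero image, with R and
C the inverse row/column sums of A (zero sums contribute zero).  λ = 1 and
no non-negativity constraint by default; both are configurable.  The
iteration count is a fixed protocol parameter, 180 by default, sitting at
the sharp end of the noise/resolution trade-off;
`optimize_iterations` sweeps that trade-off (noise SD and MTF50 both
increase monotonically with the count on simulated data).  On a small
consistent system the iterate matches the dense row-weighted least-squares
solution to < 1e−4.  Because running SIRT far into convergence amplifies
high-frequency noise, SIRT images at 180 iterations are *noisier* but
*sharper* than FBP images of the same acquisitions — the directionality the
study design expects, and one the test suite asserts.

The two algorithms reconstruct onto different grids, mirroring protocols
that store FBP and iterative reconstructions at different pitches (desk
scale: 128² at 0.25 mm for FBP, 160² at 0.2 mm for SIRT —
the same 0.125/0.1 pitch ratio as the full-size matrices).  All ROI
measurements are therefore defined in world millimetres, never voxel
indices.

**HU calibration** uses the reconstructed water phantom of the same
algorithm: HU = 1000(μ − μ_water)/μ_water with μ_water the measured mean in
a centred ROI.

## Noise removal

The 3D bilateral filter weights each window voxel by the product of a
spatial Gaussian (σ_spatial, mm, spacing-aware) and an intensity Gaussian
(σ_range, HU); windows are truncated at the volume boundary and
renormalised.  Parameters are tied to the measured image properties of
each reconstruction algorithm: σ_range = c_r·(noise SD) and
σ_spatial = c_s·(PSF FWHM from MTF50), with surrogate defaults c_r = 2,
c_s = 1 (the constants used with the physical scanner are not public).
The filter is a convex combination, so output values are bounded by the
input range; in the large-σ_range limit it reduces to a truncated Gaussian
convolution (verified to 1e−6), and on a noiseless two-level step the 50%
crossing moves by < 0.25 voxel.

One behaviour worth noting: on the *gradual* edge of a SIRT reconstruction
the range kernel suppresses averaging across the transition and steepens
it (the well-known bilateral "cartooning" effect), so the measured MTF50 of
fSIRT can come out ~10–15% *higher* than SIRT.  The filter preserves
resolution in the sense that matters — it never degrades it while removing
noise — and the suite asserts exactly that one-sided property.

## Image-quality metrology

* **NPS**: square ROIs from the uniform water region (half-overlapping
  stride grid, every slice), per-ROI 2nd-order 2D polynomial detrend,
  |FFT|²·ΔxΔy/(NxNy), ensemble average; the 1D curve is a radial average in
  annuli one frequency sample wide.  Parseval closure (∫NPS = variance) is
  verified to 5% on white noise.
* **MTF**: edge method on the semi-cylinder's flat face — per-row 50%
  crossings → fitted edge line → signed-distance binning of all ROI pixels
  at 4× sub-pixel oversampling → ESF → derivative → Hann window centred on
  the LSF peak → |FFT| normalised at f = 0; MTF50 and MTF10 by
  interpolation.  Against an analytically Gaussian-blurred edge the curve
  matches exp(−2π²σ²f²) within 3% down to the 10% modulation point.
* **CNR**: contrast of each level's subtracted image relative to the
  0 mg I/ml subtracted image, divided by the noise of the 0-level
  subtracted image.  "Noise" is read as the voxel SD within the measurement
  ROI of that image; the alternative reading (SD of ROI means across
  replicates) is available behind a flag, since "standard deviation of the
  mean value" admits both.  An in-vivo-style CNR relative to a
  muscle ROI is provided for C_I maps.

## Study design and statistics

Each session acquires one baseline scan of the 0 mg I/ml phantom plus
n_replicates scans of every level (defaults: 3 replicates × 2 sessions,
mimicking a test–retest design).  Each acquisition gets an independent
noise realisation with a seed derived as
SeedSequence([master, session, slot, level]); the same noisy sinogram feeds
both reconstruction algorithms, as in a real scan reconstructed twice.
Per scenario, each level's image is registered (phase-correlation
translation by default; full affine refinement available) to the session
baseline, subtracted, and measured in a 3 mm spherical ROI centred in the
insert.

The ΔHU→C_I calibration is fitted by ordinary least squares per
*reconstruction algorithm* on the session-0 level means and shared with the
filtered scenario of that algorithm, so the study uses exactly two
calibration functions (FBP and SIRT).  The intercept is retained.

Accuracy and precision metrics follow quantitative-imaging-biomarker
practice:

* bias = measured − nominal, per replicate and per-level mean;
* linearity: 1st- and 2nd-order polynomial fits of measured on nominal
  (replicates pooled); pass ⇔ β₂ < 0.5, 0.95 < β₁ < 1.05, R² > 0.9;
* repeatability: per-level wSD (sample SD, n−1), wCV = wSD/mean (flagged
  NaN at a zero-mean level), RC = 2.77·wSD; pooled wSD is the RMS of the
  per-level wSDs (per-level values are always retained);
* reproducibility: Pearson r between scenarios, measurements paired by
  (session, replicate, level) — the only deterministic pairing available.

Hypothesis tests comparing scenarios (ANOVA, Friedman, etc.) are out of
scope; the report retains all raw measurements so any standard test can be
applied downstream.

## Problem sizes and numerical choices

The desk-scale defaults (128²/160² in-plane, 8 slices, 200 angles, 180
SIRT iterations) were chosen so the complete four-scenario study runs in
single-digit minutes on one CPU while exercising every algorithm at
realistic noise levels; the full-protocol sizes are exposed via
`StudyConfig.full_scale()`.  SIRT reconstructions of a session are batched
as stacked right-hand-side columns of one sparse-matrix run, which is
mathematically identical to per-volume runs.  Voxelization supersamples
voxels 4× per axis for area-weighted boundaries.  Reports round floats to
10 significant decimals and sort keys, so a fixed-seed study serialises to
byte-identical JSON across runs.

## What the simulation does and does not show

The simulator reproduces the *structure* of the physical experiment —
counting noise, algorithm-specific noise/resolution behaviour, the
two-grid geometry, the test–retest replicate design — so passing tests
demonstrate that the quantification chain is linear, unbiased and
repeatable under those conditions, and that the comparative directions
(SIRT noisier and sharper than FBP at high iteration counts; bilateral
filtering removing noise without resolution loss; near-perfect
cross-scenario reproducibility) emerge from the pipeline itself.  It does
not reproduce scanner-specific magnitudes: no polychromatic spectrum, no
scatter, no detector non-idealities, no cone-beam geometry, no anatomical
background, no motion.  Absolute bias/RC magnitudes and calibration
coefficients therefore characterise the simulated system, not any physical
scanner; only the linearity and reproducibility claims are expected to
carry over quantitatively.
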