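# cisubquant

Accuracy and precision of iodine quantification in **subtracted
contrast-enhanced micro-CT**, evaluated end-to-end on a simulated
four-scenario phantom study.

In subtracted CE micro-CT a baseline scan is subtracted voxelwise from a
contrast-enhanced scan, and the remaining signal ΔHU is converted to iodine
concentration C_I (mg I/ml) through a linear calibration
C_I = a·ΔHU + b fitted on calibrated iodinated phantoms.  Whether C_I is a
usable quantitative imaging biomarker depends on the processing chain:
the reconstruction algorithm — analytic filtered backprojection (FBP) vs.
the simultaneous iterative reconstruction technique (SIRT),
x ← x + λ·C·Aᵀ·R·(p − A·x) — and edge-preserving noise removal with a 3D
bilateral filter (BF), giving four scenarios: FBP, fFBP, SIRT, fSIRT.

This package implements the whole chain against a digital phantom
simulator, so every stage is verifiable without scanner data:

* digital phantoms (water cylinder, acrylic semi-cylinder edge, calibrated
  iodinated inserts at 0/0.5/1.0/3.0 mg I/ml) voxelized with area-weighted
  boundaries;
* parallel-beam Joseph projection with transmission Poisson noise,
  materialised as a sparse operator whose transpose is the exact SIRT
  backprojector;
* FBP (apodized ramp) and SIRT (180 iterations by default) on their own
  voxel grids, HU calibration against a water phantom;
* per-algorithm 3D bilateral filtering with parameters tied to measured
  noise and resolution;
* registration, subtraction, C_I calibration, world-coordinate ROI
  measurement;
* image-quality metrology (2D/1D NPS, edge-method MTF, CNR) and biomarker
  statistics: bias, linearity (β₂ < 0.5, 0.95 < β₁ < 1.05, R² > 0.9),
  repeatability (wSD, wCV = wSD/mean, RC = 2.77·wSD) and cross-scenario
  Pearson reproducibility.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Run the desk-scale study (four scenarios, levels 0/0.5/1/3 mg I/ml,
3 replicates × 2 sessions, 200 angles, I0 = 1e5 photons/bin, master seed
42; ≈ 7 minutes on one CPU):

```python
from cisubquant.pipeline import StudyConfig, run_phantom_study, export_report

report = run_phantom_study(StudyConfig())
export_report(report, "results/")
for scen, blk in report.scenarios.items():
    print(scen, "R2", round(blk["linearity"]["r_squared"], 6),
          "noise_sd", round(blk["noise_sd"], 2),
          "mtf50", round(blk["mtf"]["mtf50"], 3),
          "pooled_RC", round(blk["repeatability"]["pooled_rc"], 4))
print({k: round(v["pearson_r"], 6) for k, v in report.reproducibility.items()})
```

prints

```text
FBP   R2 0.99999   noise_sd 8.79   mtf50 0.825  pooled_RC 0.011
fFBP  R2 0.999992  noise_sd 2.9    mtf50 0.838  pooled_RC 0.0093
SIRT  R2 0.999977  noise_sd 23.82  mtf50 1.557  pooled_RC 0.0143
fSIRT R2 0.999985  noise_sd 8.51   mtf50 1.757  pooled_RC 0.0121
{'FBP_vs_SIRT': 0.99999, 'FBP_vs_fFBP': 0.999994,
 'SIRT_vs_fSIRT': 0.999997, 'fFBP_vs_fSIRT': 0.999995}
```

Reading the numbers: measured C_I is linear in nominal C_I in every
scenario (R² ≫ 0.95); SIRT at 180 iterations is noisier (23.8 vs 8.8 HU)
but sharper (MTF50 1.56 vs 0.83 lp/mm) than FBP; the bilateral filter cuts
the noise by ~3× in both algorithms without losing resolution; the
repeatability coefficient (the 95% limit for the difference of two repeated
measurements) is of order 0.01 mg I/ml at these ROI sizes; and measurements
are almost perfectly reproducible across scenarios (Pearson r > 0.999).

The same study is available from the shell:

```sh
cisubquant study --out results/          # full four-scenario study
cisubquant qc --out qc.json              # NPS / MTF / noise only
cisubquant simulate --kind iodine_set --levels 0,0.5,1,3 --out phantoms/
cisubquant evaluate --measurements results/measurements.csv --out metrics.json
```

`cisubquant evaluate` accepts any replicate-measurement CSV with columns
`scenario,nominal_ci,replicate,session,measured_ci`, so the statistics
module can be applied to real scanner measurements.

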