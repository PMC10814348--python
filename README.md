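# hp13c

Analysis tools for **dynamic hyperpolarized [1-¹³C]pyruvate brain MRI**.

Hyperpolarized ¹³C MRI transiently boosts the signal of an injected
[1-¹³C]pyruvate tracer ~10⁴-fold, making it possible to watch, over about a
minute, its in-vivo conversion to [1-¹³C]lactate (glycolysis, elevated in
tumors via the Warburg effect) and [¹³C]bicarbonate (oxidative
decarboxylation).  The quantities of interest are the apparent first-order
rate constants **k_PL** (pyruvate→lactate) and **k_PB**
(pyruvate→bicarbonate), mapped voxelwise from a dynamic multichannel EPI
acquisition (20 timepoints × 3 s, metabolite-selective flips of
20°/30°/30°).  This package implements the full analysis chain for such
data, aimed at researchers processing dynamic HP-¹³C studies or validating
acquisition protocols:

- **`hp13c.synth`** — seeded synthetic data: a mirror-symmetric digital brain
  phantom with NAWM / T2-lesion / tumor ROIs, a gamma-variate pyruvate
  bolus, the two-site exchange forward model with per-metabolite RF losses,
  and multichannel complex data with a full channel noise covariance.
- **`hp13c.preproc`** — noise-covariance estimation, Cholesky prewhitening,
  pyruvate-weighted matched-filter channel combination, zero-order phasing,
  higher-order-SVD (HOSVD) tensor denoising, and SNR-thresholded AUC maps.
- **`hp13c.kinetics`** — voxelwise *inputless* kinetic modeling: the measured
  pyruvate signal drives discrete lactate/bicarbonate updates

  `M_X(i+1) = M_X(i)·cos(α_X)·e^(−Δt/T1_X) + k_PX·∫ P dt`,

  with k_PL, k_PB fitted jointly by bounded least squares, residual-based
  fractional errors, the ≤25 % error filter, and >30 %-NAWM regional
  summaries.
- **`hp13c.inflow`** — the pyruvate inflow-capture percentage
  `%Inflow = (Pyr_max − (Pyr_0 − Pyr_min)) / (Pyr_max − Pyr_min) × 100`
  and an acquisition-delay simulation (0.1-s shifted, 3-s resampled traces
  with recomputed kinetics).
- **`hp13c.asym`** — the hemispheric asymmetry statistic: maps are 2×
  in-plane interpolated, z-normalized, symmetric-masked; each point's
  3×3-patch + weighted-coordinate feature is matched to its best
  opposite-hemisphere counterpart, `s(p) = min_q ‖f_p − f_q‖`, and
  `S = mean(s)` (0 ⇔ perfect mirror correspondence).
- **`hp13c.coverage`** — oriented-box imaging prescriptions, Dice overlap
  `2|A∩B|/(|A|+|B|)` for serial-coverage consistency, and partial-volume ROI
  fractions.
- **`hp13c.acquisition`** — pyruvate center-frequency referencing (urea:
  +270 Hz; water: ×0.251491899), the Gaussian model of the 130-Hz-FWHM
  spectral-spatial excitation, phase-encode voxel bandwidth / pixel-shift
  calculators, dynamic timing, and the injection QC gate.
- **`hp13c.pipeline` / `hp13c.cli`** — seeded end-to-end orchestration and a
  thin `hp13c` command (`demo`, `synth`, `acq f0`, `dice`).

## Worked example

```bash
python examples/full_pipeline_demo.py
```

```
NAWM k_PL = 0.0152 +/- 0.0004 1/s over 449 voxels
NAWM k_PB = 0.0030 +/- 0.0001 1/s
  (ground truth: 0.015 and 0.003 1/s)
%Inflow over NAWM = 102.2%  (>100% means the trace starts at zero but retains tail signal)
Global asymmetry S = 0.0012  (near 0: symmetric phantom)
Serial Dice, atlas-anchored vs fixed-axis prescription under a simulated head rotation: 1.000 vs 0.940
```

The pipeline synthesized an 8-channel dynamic dataset on a 16×16×8 phantom
whose brain was assigned k_PL = 0.015 s⁻¹ and k_PB = 0.003 s⁻¹, pushed it
through prewhitening → combination → phasing → denoising → fitting, and
recovered the ground-truth rates within ~1 % in normal-appearing white
matter.  The near-zero asymmetry score reflects the phantom's hemispheric
symmetry (its one-sided lesion is excluded together with its mirror image),
and the Dice pair shows why an anatomy-anchored prescription keeps serial
coverage consistent while a fixed scanner-axis prescription loses overlap
when the head turns.  Other examples (`examples/*.py`) demonstrate
single-voxel fitting, the delay sweep, asymmetry scoring, and the
acquisition utilities, each printing a few annotated numbers.

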