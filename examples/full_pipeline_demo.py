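"""End-to-end demonstration on a seeded synthetic brain dataset.

Builds a mirror-symmetric digital phantom with NAWM / lesion / tumor
ROIs, synthesizes 8-channel complex dynamic data with correlated noise,
runs the preprocessing chain (prewhitening, channel combination,
phasing, HOSVD denoising, SNR-thresholded AUC maps), fits voxelwise
k_PL / k_PB maps with the <=25% error filter, and summarizes NAWM
kinetics, pyruvate inflow, hemispheric asymmetry, and prescription
coverage.
"""

from hp13c import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1))

reg = res["regional_kinetics"]
print(f"NAWM k_PL = {reg['k_pl_mean']:.4f} +/- {reg['k_pl_sd']:.4f} 1/s over {reg['n']} voxels")
print(f"NAWM k_PB = {reg['k_pb_mean']:.4f} +/- {reg['k_pb_sd']:.4f} 1/s")
print("  (ground truth: 0.015 and 0.003 1/s)")
print(f"%Inflow over NAWM = {res['inflow'].percent_inflow:.1f}%  "
      "(>100% means the trace starts at zero but retains tail signal)")
print(f"Global asymmetry S = {res['asymmetry'].S:.4f}  (near 0: symmetric phantom)")
cov = res["coverage"]
print(f"Serial Dice, atlas-anchored vs fixed-axis prescription under a "
      f"simulated head rotation: {cov['dice_atlas']:.3f} vs {cov['dice_fixed']:.3f}")
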