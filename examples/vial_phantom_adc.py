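"""Six-vial phantom study: simulate, reconstruct, map ADC, regress.

Builds the six-vial diffusion phantom, acquires b = 0 and b = 500 s/mm^2
volumes with the multi-shot DP-GRE simulator (4 coils, no noise),
reconstructs with navigator phase correction, fits the two-point ADC map,
and prints the per-vial means with the measured-vs-reference regression —
the accuracy summary a phantom QA study reports.
"""

import numpy as np

import dpgre
from dpgre.adcfit import fit_adc, label_stats, reference_regression

ADCS = [0.4e-3, 0.6e-3, 0.8e-3, 1.1e-3, 1.5e-3, 2.0e-3]

vol = dpgre.make_vial_phantom(6, ADCS, grid_shape=(64, 32, 8))
cfg = dpgre.SequenceConfig(lines_per_shot=32, n_partitions=8, averages=(1, 1))
sens = dpgre.make_coil_sens(4, (64, 32), seed=5)

acq = dpgre.simulate_acquisition(vol, cfg, coil_sens=sens, seed=1)
volumes = dpgre.reconstruct(acq, correct=True)

res = fit_adc(volumes[0.0].magnitude, volumes[500.0].magnitude, 500.0)
stats = label_stats(res, vol.labels, margin_vox=1)  # interior ROIs, QA style

print("vial   reference      measured (mm^2/s)")
for lab, truth in zip(sorted(stats), ADCS):
    print(f"  {lab}    {truth:.2e}    {stats[lab]['mean']:.6e}  "
          f"(n={stats[lab]['n_voxels']})")

fit = reference_regression([stats[k]["mean"] for k in sorted(stats)], ADCS)
print(f"\nmeasured vs reference: slope {fit['slope']:.4f}, "
      f"intercept {fit['intercept']:.2e} mm^2/s, "
      f"R^2 {fit['r_squared']:.6f}, RMSE {fit['rmse']:.2e} mm^2/s")
print("slope ~ 1 and intercept ~ 0 mean the sequence measures diffusion, "
      "not T1/T2 contamination.")
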