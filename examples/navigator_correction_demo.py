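"""What the 2D navigator buys: intershot phase-error correction.

Injects per-shot phase errors (constant, constant+linear, and smooth
band-limited fields) into a zero-noise acquisition of the six-vial
phantom, reconstructs with and without the navigator conjugate-phase
correction, and prints the NRMSE against the error-free reconstruction.
Uncorrected multi-shot diffusion data ghosts along the partition
direction; the navigator removes the shot-to-shot inconsistency.
"""

import numpy as np

import dpgre
from dpgre.recon import nrmse

vol = dpgre.make_vial_phantom(
    6, [0.4e-3, 0.6e-3, 0.8e-3, 1.1e-3, 1.5e-3, 2.0e-3], grid_shape=(64, 32, 8)
)
cfg = dpgre.SequenceConfig(lines_per_shot=32, n_partitions=8, averages=(1, 1))
sens = dpgre.make_coil_sens(4, (64, 32), seed=5)

clean = dpgre.simulate_acquisition(vol, cfg, coil_sens=sens, seed=1)
ref = np.abs(dpgre.reconstruct(clean, correct=True)[0.0].data)

print("phase errors        corrected      uncorrected   (NRMSE vs error-free)")
for kind in ("constant", "linear", "smooth"):
    pm = dpgre.PhaseErrorModel(kind=kind, seed=3)
    acq = dpgre.simulate_acquisition(vol, cfg, coil_sens=sens, phase_model=pm, seed=1)
    e_c = nrmse(np.abs(dpgre.reconstruct(acq, correct=True)[0.0].data), ref)
    e_u = nrmse(np.abs(dpgre.reconstruct(acq, correct=False)[0.0].data), ref)
    print(f"  {kind:<16}  {e_c:.2e}      {e_u:.2e}")

print("\nConstant errors are removed exactly; linear errors leave a small")
print("residual because the shifted spectrum interacts with the centric")
print("T1-train weighting; smooth in-band fields recover to percent level.")
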