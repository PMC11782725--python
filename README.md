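# dpgre

Desk-scale simulator and reconstruction pipeline for **3D reduced-FOV
diffusion-prepared gradient-echo (DP-GRE) MRI** with magnitude stabilizers
and 2D navigator phase correction.

## The problem

Diffusion-weighted imaging of the cervical spinal cord with single-shot EPI
suffers severe geometric distortion near bone/tissue susceptibility
gradients. An alternative is to *prepare* the diffusion contrast before an
undistorted readout: a 90° tip-down, bipolar diffusion gradients around two
refocusing pulses, and a 90° tip-up that stores the diffusion-attenuated
magnetization along z, followed by a centric multi-shot 3D spoiled
gradient-echo train (one k-space partition per shot, reduced phase FOV).
Two problems follow, and this package models both and their solutions:

1. **Motion phase → magnitude loss.** Bulk motion during the diffusion
   gradients gives each shot a spatially varying phase θᵢ(x, y); a plain
   tip-up converts it into irrecoverable magnitude modulation. A *magnitude
   stabilizer* — a dephasing gradient before the tip-up, rewound after each
   readout excitation — selects a stimulated-echo pathway that converts
   θᵢ into ordinary image phase instead, at the cost of half the signal:

   A_prep = mz · ½ · e^(−TE_prep/T2) · e^(−b·ADC) · e^(−iθ)

2. **Intershot phase inconsistency.** The surviving per-shot phase still
   ghosts the multi-shot combination. Each shot therefore appends a
   low-resolution 2D navigator with the same phase corruption; after
   Hamming apodization and inverse Fourier transform, each shot image is
   corrected per coil by

   S_corr(x, y) = S(x, y) · N*(x, y) / |N(x, y)|

   before the final transform along the partition direction.

Because the stabilizer spoils whatever the tip-up does not store, the
longitudinal steady state before every shot is *independent of b*, so a
two-point mono-exponential fit, ADC = ln(S₀/S_b)/b, recovers the apparent
diffusion coefficient without T1 bias — the property that makes DP-GRE
quantitative.

The package contains the isochromat-level signal engine, digital phantoms
(a six-vial diffusion phantom and a sagittal cervical-cord object), the
multi-shot k-space simulator with coil sensitivities / noise / intershot
phase-error models, the navigator-corrected reconstruction, and the ADC
mapping with phantom-QA regression. It is aimed at sequence developers and
reconstruction researchers who want a controlled testbed where the ground
truth is known exactly.

## Worked example

`examples/vial_phantom_adc.py` simulates a zero-noise six-vial phantom
acquisition (b = 0 / 500 s/mm², 4 coils, 8 partitions), reconstructs with
navigator correction and fits the ADC map:

```
vial   reference      measured (mm^2/s)
  1    4.00e-04    4.165336e-04  (n=152)
  2    6.00e-04    6.138384e-04  (n=128)
  3    8.00e-04    8.131323e-04  (n=128)
  4    1.10e-03    1.110360e-03  (n=152)
  5    1.50e-03    1.504566e-03  (n=128)
  6    2.00e-03    1.994477e-03  (n=128)

measured vs reference: slope 0.9867, intercept 2.30e-05 mm^2/s,
R^2 0.999992, RMSE 1.49e-06 mm^2/s
```

A slope of ~1 with near-zero intercept is the phantom-QA signature that the
sequence measures diffusion rather than relaxation contamination; the small
per-vial deviations come from the centric-train point-spread function
mixing bath signal into vial edges (see `docs/methods.md`).

The other examples print the stimulated-echo signal cost and steady-state
b-independence (`stimulated_echo_cost.py`) and the corrected/uncorrected
NRMSE under constant, linear and smooth intershot phase errors
(`navigator_correction_demo.py`).

A CLI mirrors the pipeline for file-based use:

```bash
dpgre phantom --type vials --out ph/
dpgre simulate --phantom ph/ --phase-model smooth --noise 0.01 --seed 7 --out data.h5
dpgre recon data.h5 --correction --out rec/
dpgre adc --b0 rec/b0_mag.nii.gz --bval 500 --dwi rec/b500_mag.nii.gz --out adc/
```

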