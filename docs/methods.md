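# Methods

## Signal model

The sequence is modelled per shot as four stages, all evaluated per voxel
on quantitative maps (PD, T1, T2, ADC):

**Diffusion preparation.** An ensemble of `n_isochromats` spins per voxel
receives stabilizer phases φⱼ = j·Δφ/n spanning the configured dispersion
(default 4π). Each isochromat is tipped down by an ideal 90°, its
transverse magnetization decays by `exp(−TE_prep/T2)·exp(−b·ADC)`,
acquires the shot's motion phase (applied as e^(−iθ); image phase is −θ
package-wide), the stabilizer phase, and is tipped up by an ideal 90° that
stores the in-phase (cosine) component along z. The recallable stimulated
echo is the ensemble component that rephases under the −φⱼ rewinder:

    A_prep = (1/n) Σⱼ a·cos(φⱼ − θ)·e^(−iφⱼ)  →  ½·a·e^(−iθ)

for any dispersion that is a whole number of turns, where
`a = mz·exp(−TE_prep/T2)·exp(−b·ADC)`. The net longitudinal magnetization
after the tip-up is Σⱼ cos(φⱼ − θ) = 0 under the same condition — the
stabilizer consumes the entire longitudinal pool. Isochromat phases are
placed at exactly j·Δφ/n so these cancellations hold to machine precision
rather than to quadrature error. Refocusing pulses are treated as ideal
(their role here is B1 robustness, not waveform shape) and diffusion
weighting is parametrized directly by b rather than by gradient waveforms.

**Readout train.** A FLASH train with flip α reads echo n as
`sin(α)·A_n·exp(−TE/T2)` while the stored amplitude evolves as
`A_{n+1} = A_n·cos(α)·exp(−Δt_esp/T1)`. The stored component is dephased
across the stabilizer moment, so it relaxes toward zero, and regrowing
magnetization never joins the stimulated-echo pathway. Echo n maps to ky
by centric ordering 0, +1, −1, +2, −2, … (positive first; for even
matrices the unpaired edge line −N/2 is last). T2* is identified with T2:
at TE = 2.36 ms there is no off-resonance model to resolve.

**Steady state.** Each shot cycle zeroes the longitudinal pool
(preparation), saturates the regrowth with `lines_per_shot + nav_lines`
readout pulses, and recovers freely for the remainder of the shot TR. The
fixed point is reached after one dummy shot and — because the preparation
consumes everything regardless of b — is identical across b-values. This
is the mechanism that makes the two-point fit exact on noiseless signal
volumes: the b500/b0 ratio is `exp(−500·ADC)` per voxel with no T1 term.

**Encoding.** Each shot partition-encodes one kz row of the centred 3D
DFT (DC at index N//2 on every axis) of the object weighted by the
reduced-FOV excitation profile and per-coil sensitivities, with the
per-line train amplitude applied in acquisition order. The navigator
re-excites the remaining stored magnetization after the imaging train
(its amplitude continues the same recursion) and samples the centre
`nav_lines` ky rows in linear order with no partition encoding — i.e. a
projection over the slab. Intershot phase errors are injected into the
prepared magnetization, so imaging data and navigator of a shot share the
same θᵢ, which is exactly what the correction relies on. Noise is i.i.d.
complex Gaussian per k-space sample, with σ specified relative to the DC
magnitude of the b = 0 object.

## Reconstruction

Per coil and shot: Hamming apodization of the navigator along its
acquired ky extent and along kx, zero-filling to the imaging matrix, 2D
inverse FFT of both navigator and shot, conjugate-phase multiplication
`S·N*/|N|`, stacking along kz, 1D inverse FFT, matched-filter coil
combination `Σ conj(s)I / Σ|s|²` (root-sum-of-squares fallback without
sensitivities), and complex averaging of repetitions (magnitude averaging
available to study its low-SNR ADC bias). Only the navigator's phase is
used, so the Hamming filter's amplitude scaling needs no renormalization.

Numerical guards: the correction phase is applied only where the
root-sum-of-squares navigator magnitude across coils exceeds
`epsilon = 0.05` of its maximum (elsewhere the pixel is left uncorrected).
The threshold is deliberately taken on the coil-combined magnitude: a
per-coil threshold would leave each coil's low-sensitivity side
uncorrected even where the array as a whole sees the object, which
measurably degrades the zero-noise recovery. Missing partitions raise an
assembly error listing the absent kz indices; a voxel with zero
sensitivity sum-of-squares combines to zero.

## Parameters

Defaults describe the protocol the simulator emulates:

| parameter | default | meaning |
|---|---|---|
| b-values | 0, 500 s/mm² | two-point diffusion weighting |
| TR_shot | 2000 ms | time between successive shots |
| TE_prep | 65 ms | diffusion preparation duration |
| flip | 10° | readout excitation |
| echo spacing | 4.21 ms | readout pulse interval |
| TE | 2.36 ms | readout echo time |
| lines/shot | 41 (phantom grid: = reduced ny) | in-plane PE per shot |
| navigator lines | 14 | centre ky rows, linear order |
| dummy shots | 1 | steady-state preparation |
| stabilizer dispersion | 4π | intra-voxel phase spread |
| isochromats | 64 | ensemble size per voxel |
| averages | 1 (b0), 5 (b500) | repetitions, complex-averaged |

Phantoms: six vials (radius 10 % of the in-plane FOV) on a hexagonal ring
inside a circular water bath; default vial ADCs 0.4–2.0 ×10⁻³ mm²/s and
bath 2.0 ×10⁻³ mm²/s (room-temperature water); vial T1/T2 = 1000/500 ms
(polymer-solution phantoms' relaxation times are not standardized — these
are configurable). The cord object is a thin strip (ADC 0.9 ×10⁻³ mm²/s)
in CSF (3.0 ×10⁻³) with vertebral blocks, plus a cord ROI.

Intershot phase-error models (per shot, reproducible from seed and shot
identity so acquisition order is irrelevant): constant offsets U(−π, π);
"linear" = constant plus gradients U(−π/2, π/2) radians across the FOV per
in-plane axis — sub-half-cycle shot-to-shot phase ramps of the kind bulk
motion produces; "smooth" = white noise hard-band-limited to a fraction
(default 0.5) of the navigator's phase-encode bandwidth, scaled to 0.3 rad
standard deviation, representing the non-rigid residual. These are the
study conditions of the validation suite, not tuning knobs.

## What the synthetic data does and does not show

The generator reproduces the features the method is *about*: stimulated
echo formation and its 50 % cost, b-independent saturation-recovery steady
state, centric T1-train modulation, reduced-FOV aliasing behaviour,
per-shot navigator/imaging phase consistency, coil sensitivity weighting,
and complex Gaussian k-space noise. It does not model susceptibility off-
resonance or EPI-style distortion (the comparison that motivates the
sequence), eddy currents, pulsatile/through-plane motion, chemical-shift
fat displacement (fat is a PD scale factor per label), slice-profile
imperfections of the adiabatic pulses, or Rician magnitude statistics of
in vivo multi-channel reconstructions. Passing tests therefore certify
the sequence/reconstruction mathematics, not in vivo robustness.

## Accuracy notes and known limitations

- **Linear phase errors are not perfectly correctable.** A linear
  intershot phase shifts the shot's in-plane spectrum by k₀ = g/2π lines,
  so the centric train weighting A(k) samples A(k)·F(k−k₀). Image-space
  conjugate correction removes the phase but cannot un-mix the shifted
  weighting; the residual (≈0.2 % NRMSE at the default gradient range,
  scaling roughly linearly with k₀) persists even when correcting with the
  ground-truth phase. Constant offsets are removed to machine precision.
- **Navigator estimates carry a common-mode ramp.** Linear-order
  navigator acquisition during train decay, and the half-sample asymmetry
  of even-length Hamming windows, give the navigator a nonzero phase that
  is identical for every shot and therefore cancels in the correction.
- **Centric-train point-spread function.** The per-line amplitude
  `cos(α)·exp(−Δt/T1)` raised to the echo index acts as an in-plane (ky)
  convolution; vial-edge voxels mix bath signal, displacing reconstructed
  per-vial mean ADC by ~10⁻⁵ mm²/s on the test grids. On the sequence's
  per-voxel signal volumes the two-point fit is exact. ROI statistics
  support in-plane erosion (`margin_vox`) to mimic QA practice of avoiding
  region edges.
- **Smooth fields beyond the navigator band are unrecoverable by design**;
  correction error grows monotonically with the field's spectral cutoff,
  and the Hamming filter attenuates even in-band content near the band
  edge.
- The two-point fit floors at 1 % of the peak b0 magnitude to keep
  background out of the logarithm; negative ADC estimates under noise are
  retained and flagged rather than clamped.
- Grids in the validation suite are 64×32×8 with 32 lines per shot (the
  protocol's 41-line column is the default for user configurations);
  isochromat counts of 16–64 are exact for these claims because the
  cancellation conditions are arithmetic, not statistical.
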