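"""Navigator-based phase-corrected reconstruction.

Per receiver coil and per shot: the navigator k-space is Hamming-apodized
(to reduce Gibbs ringing of the low-resolution phase estimate), zero-filled
to the imaging in-plane matrix and inverse-Fourier-transformed; the imaging
shot is inverse-transformed likewise; the shot image is multiplied by the
unit-magnitude conjugate of the navigator image,

    S_corr(x, y) = S(x, y) * conj(N(x, y)) / |N(x, y)|,

which removes the shot's intershot phase while leaving its magnitude
untouched.  Corrected partitions are stacked along kz, a final centred
inverse transform along the partition axis yields the 3D volume, coils are
combined, and repetitions are complex-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import AssemblyError, SignalError
from .fourier import icfft, icfft2
from .seqsim import SequenceConfig

__all__ = [
    "NavigatorImage",
    "ReconVolume",
    "hamming_window",
    "hamming_apodize",
    "nav_to_image",
    "shot_to_image",
    "phase_correct_shot",
    "coil_combine",
    "combine_shots",
    "reconstruct",
    "nrmse",
    "save_volume",
]


@dataclass
class NavigatorImage:
    """Complex per-coil navigator image on the imaging in-plane grid."""

    data: np.ndarray          # (n_coils, nx, ny)
    filter_applied: bool = True


@dataclass
class ReconVolume:
    """Reconstructed complex volume for one b-value."""

    data: np.ndarray          # (nx, ny, nz)
    b_value: float
    meta: dict = field(default_factory=dict)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)


def hamming_window(m: int) -> np.ndarray:
    """w(k) = 0.54 - 0.46 cos(2 pi k / (m - 1)); maximum 1 at the centre."""
    if m < 2:
        raise SignalError("Hamming window needs at least 2 samples")
    return 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(m) / (m - 1))


def hamming_apodize(nav_kspace: np.ndarray) -> np.ndarray:
    """Separable Hamming apodization of navigator k-space.

    Applied along the acquired ky extent (length ``nav_lines``) and along
    the full kx axis; shape (n_coils, nav_lines, nx) is preserved.
    """
    nav_kspace = np.asarray(nav_kspace)
    n_lines, nx = nav_kspace.shape[-2], nav_kspace.shape[-1]
    w_ky = hamming_window(n_lines)
    w_kx = hamming_window(nx)
    return nav_kspace * w_ky[:, None] * w_kx[None, :]


def _assemble(lines: np.ndarray, ny: int, row_offsets: np.ndarray) -> np.ndarray:
    """Place ky lines (..., n_lines, nx) onto a (..., nx, ny) k-grid."""
    shape = lines.shape[:-2] + (lines.shape[-1], ny)
    grid = np.zeros(shape, dtype=complex)
    for i, off in enumerate(row_offsets):
        grid[..., :, ny // 2 + off] = lines[..., i, :]
    return grid


def nav_to_image(nav_kspace_filtered: np.ndarray, target_shape: tuple) -> NavigatorImage:
    """Zero-fill the navigator to the imaging in-plane grid and transform.

    ``target_shape`` is ``(nx, ny)`` of the reduced imaging matrix.  The
    acquired lines are the centre-most ky rows in linear order.
    """
    nx, ny = target_shape
    nav = np.asarray(nav_kspace_filtered)
    if nav.ndim == 2:
        nav = nav[None]
    n_lines = nav.shape[-2]
    if nav.shape[-1] != nx:
        raise ValueError("navigator kx extent does not match the imaging grid")
    if n_lines > ny:
        raise ValueError("navigator has more ky lines than the imaging matrix")
    offsets = np.arange(n_lines) - n_lines // 2
    grid = _assemble(nav, ny, offsets)
    return NavigatorImage(data=icfft2(grid), filter_applied=True)


def shot_to_image(kspace: np.ndarray) -> np.ndarray:
    """Per-coil in-plane image of one imaging shot, (n_coils, nx, ny)."""
    kspace = np.asarray(kspace)
    n_lines = kspace.shape[-2]
    offsets = np.arange(n_lines) - n_lines // 2
    grid = _assemble(kspace, n_lines, offsets)
    return icfft2(grid)


def phase_correct_shot(
    shot_image: np.ndarray,
    nav_image: NavigatorImage | np.ndarray,
    epsilon: float = 0.05,
) -> np.ndarray:
    """Conjugate-phase correction of one shot by its navigator.

    Wherever the navigator carries signal the shot is multiplied per coil
    by ``conj(N)/|N|``; the per-pixel magnitude of the shot is never
    altered.  Reliability is judged on the root-sum-of-squares navigator
    magnitude across coils: pixels below ``epsilon`` times its maximum are
    left uncorrected (correction phase 0).  A combined-magnitude guard —
    rather than a per-coil one — keeps each coil's low-sensitivity side
    correctable wherever any coil still sees the object.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    nav = nav_image.data if isinstance(nav_image, NavigatorImage) else np.asarray(nav_image)
    shot = np.asarray(shot_image)
    if nav.shape != shot.shape:
        raise ValueError("shot and navigator shapes differ")
    mag = np.abs(nav)
    if mag.ndim > 2:  # leading axis is coils
        sos = np.sqrt(np.sum(mag**2, axis=0, keepdims=True))
    else:
        sos = mag
    reliable = sos >= epsilon * sos.max()
    phase = np.where(reliable, np.divide(nav, mag, out=np.ones_like(nav), where=mag > 0), 1.0)
    return shot * np.conj(phase)


def coil_combine(images: np.ndarray, coil_sens: np.ndarray | None = None) -> np.ndarray:
    """Combine per-coil images into one complex image.

    With known sensitivities a matched filter ``sum(conj(s) I) / sum(|s|^2)``
    is used (zero where the sensitivity sum-of-squares vanishes).  Without
    them, root-sum-of-squares magnitude with the phase of the first coil is
    returned — reliable in magnitude only.
    """
    images = np.asarray(images)
    if images.shape[0] < 1:
        raise ValueError("need at least one coil")
    if coil_sens is not None:
        sens = np.asarray(coil_sens)
        while sens.ndim < images.ndim:
            sens = sens[..., None]
        sos = np.sum(np.abs(sens) ** 2, axis=0)
        num = np.sum(np.conj(sens) * images, axis=0)
        return np.divide(num, sos, out=np.zeros_like(num), where=sos > 0)
    mag = np.sqrt(np.sum(np.abs(images) ** 2, axis=0))
    return mag * np.exp(1j * np.angle(images[0]))


def combine_shots(
    shots: list,
    cfg: SequenceConfig,
    coil_sens: np.ndarray | None = None,
    correct: bool = True,
    epsilon: float = 0.05,
    coil_method: str = "matched",
    averaging: str = "complex",
) -> ReconVolume:
    """Reconstruct one b-value volume from its shots.

    Per average: every partition must be present exactly once; each shot is
    transformed in-plane, phase-corrected per coil by its navigator (unless
    ``correct=False``), stacked along the partition axis and transformed
    along kz; coils are then combined.  Averages are combined complexly by
    default, or as magnitudes with ``averaging='magnitude'`` (offered for
    studying the low-SNR ADC bias of magnitude averaging).
    """
    if not shots:
        raise AssemblyError("no shots to combine", missing=range(cfg.n_partitions))
    b = shots[0].b_value
    nz = cfg.n_partitions
    averages = sorted({s.average_index for s in shots})
    volumes = []
    for avg in averages:
        by_kz = {s.kz: s for s in shots if s.average_index == avg}
        missing = [kz for kz in range(nz) if kz not in by_kz]
        if missing:
            raise AssemblyError(
                f"b={b} average {avg} is missing partitions {missing}", missing=missing
            )
        planes = []
        for kz in range(nz):
            s = by_kz[kz]
            img = shot_to_image(s.kspace)                      # (nc, nx, ny)
            if correct:
                nav = nav_to_image(hamming_apodize(s.nav_kspace), img.shape[-2:])
                img = phase_correct_shot(img, nav, epsilon)
            planes.append(img)
        hybrid = np.stack(planes, axis=-1)                     # (nc, nx, ny, nkz)
        per_coil = icfft(hybrid, axis=-1)
        sens = None
        if coil_method == "matched":
            if coil_sens is None:
                raise ValueError("matched-filter combination needs coil sensitivities")
            sens = _sens_on_reduced_grid(coil_sens, per_coil.shape[-3:-1])
        volumes.append(coil_combine(per_coil, sens))
    stackv = np.stack(volumes, axis=0)
    if averaging == "complex":
        data = stackv.mean(axis=0)
    elif averaging == "magnitude":
        data = np.abs(stackv).mean(axis=0).astype(complex)
    else:
        raise ValueError(f"unknown averaging '{averaging}'")
    return ReconVolume(
        data=data, b_value=b,
        meta={"coil_method": coil_method, "averaging": averaging,
              "corrected": correct, "n_averages": len(averages)},
    )


def _sens_on_reduced_grid(coil_sens: np.ndarray, target_inplane: tuple) -> np.ndarray:
    """Crop full-grid sensitivities to the central reduced phase FOV."""
    nc, nx, ny_full = coil_sens.shape
    tx, ty = target_inplane
    if (nx, ny_full) == (tx, ty):
        return coil_sens
    if nx != tx or ny_full < ty:
        raise ValueError("coil sensitivities do not match the reconstruction grid")
    start = ny_full // 2 - ty // 2
    return coil_sens[:, :, start : start + ty]


def reconstruct(acq, correct: bool = True, epsilon: float = 0.05,
                coil_method: str = "matched", averaging: str = "complex") -> dict:
    """Reconstruct every b-value of an AcquisitionSet; returns {b: ReconVolume}."""
    out = {}
    for b in acq.cfg.b_values_s_per_mm2:
        out[b] = combine_shots(
            acq.shots_for(b), acq.cfg,
            coil_sens=acq.coil_sens, correct=correct, epsilon=epsilon,
            coil_method=coil_method, averaging=averaging,
        )
    return out


def nrmse(x: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square error normalized by the reference's RMS value."""
    x = np.asarray(x)
    reference = np.asarray(reference)
    denom = np.linalg.norm(reference.ravel())
    if denom == 0:
        raise ValueError("reference is identically zero")
    return float(np.linalg.norm((x - reference).ravel()) / denom)


def save_volume(vol: ReconVolume, out_dir, tag: str, voxel_size_mm=(1.0, 1.0, 1.0)) -> dict:
    """Write magnitude / real / imaginary NIfTI volumes for one b-value."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    paths = {}
    for name, arr in (
        ("mag", np.abs(vol.data)),
        ("real", vol.data.real),
        ("imag", vol.data.imag),
    ):
        p = out_dir / f"{tag}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), p)
        paths[name] = p
    return paths
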