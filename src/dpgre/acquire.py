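"""Multi-shot 3D Cartesian k-space acquisition.

Each shot acquires every in-plane phase-encode (ky) line of a single
partition (kz) with centric ordering, then re-excites the remaining stored
magnetization to sample a low-resolution 2D navigator (centre ky lines,
linear order, no partition encoding — a projection over the slab).  The
excitation is restricted in the phase-encode direction by a slab-selective
profile (reduced FOV), so a smaller ky matrix can be sampled alias-free.

Intershot phase errors — the motion-induced phase picked up during the
diffusion gradients — are injected into the *prepared* magnetization, so
the imaging data and the navigator of the same shot share the same phase
map: exactly the property the navigator correction relies on.

K-space arrays are stored with lines in ascending ky-row order (DC at row
``n // 2``); the centric acquisition order enters through the per-line
T1-train amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import ConfigurationError
from .fourier import cfft2
from .phantom import TissueVolume
from .seqsim import SequenceConfig, centric_order, prep_amplitude, steady_state_mz

__all__ = [
    "PhaseErrorModel",
    "ShotRecord",
    "AcquisitionSet",
    "reduced_fov_profile",
    "make_coil_sens",
    "simulate_acquisition",
    "encode_partition",
    "save_acquisition",
    "load_acquisition",
]


def reduced_fov_profile(ny: int, fov_phase_fraction: float, mode: str = "ideal") -> np.ndarray:
    """Excitation weight along the phase-encode axis.

    ``ideal`` gives a rect window of width ``fraction * ny`` centred on the
    grid.  ``sinc`` computes the small-tip profile of a Hamming-windowed
    sinc tip-down pulse with time-bandwidth product 12 (the pulse used for
    the slab-selective excitation), scaled to unit passband.
    """
    if not (0.0 < fov_phase_fraction <= 1.0):
        raise ValueError("fov_phase_fraction must lie in (0, 1]")
    if mode == "ideal":
        width = max(1, round(fov_phase_fraction * ny))
        profile = np.zeros(ny)
        start = ny // 2 - width // 2
        profile[start : start + width] = 1.0
        return profile
    if mode == "sinc":
        tbw = 12.0
        nt = 1024
        tau = (np.arange(nt) + 0.5) / nt - 0.5  # normalized time in [-1/2, 1/2)
        b1 = np.hamming(nt) * np.sinc(tbw * tau)
        width = fov_phase_fraction * ny
        u = (np.arange(ny) - ny // 2) / width   # slab edges at u = +/- 1/2
        # Small-tip response: Fourier transform of the pulse at the
        # slab-position-dependent off-resonance frequency.
        phase = np.exp(2j * np.pi * tbw * np.outer(u, tau))
        profile = np.abs(phase @ b1)
        centre = np.abs(b1.sum())
        return profile / centre
    raise ValueError(f"unknown profile mode '{mode}'")


@dataclass
class PhaseErrorModel:
    """Per-shot intershot phase-error generator.

    ``kind`` selects the spatial structure of the shot phase map
    ``theta_i(x, y)``:

    - ``none``: zero phase.
    - ``constant``: a single offset drawn from ``constant_range`` (rad).
    - ``linear``: a constant offset plus linear gradients in x and y drawn
      from ``gradient_range`` (radians across the FOV).
    - ``smooth``: a band-limited random field.  ``smooth_cutoff_frac`` is
      the spectral cutoff as a fraction of the navigator's phase-encode
      bandwidth (0.5 by default: safely within what the navigator can
      resolve); ``smooth_amplitude_rad`` is the field's standard deviation.

    Maps are reproducible: each shot's field depends only on ``seed`` and
    the shot's (b index, average, partition) key, never on the order in
    which shots are simulated.
    """

    kind: str = "none"
    constant_range: tuple = (-np.pi, np.pi)
    gradient_range: tuple = (-np.pi / 2, np.pi / 2)
    smooth_cutoff_frac: float = 0.5
    smooth_amplitude_rad: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "constant", "linear", "smooth"):
            raise ConfigurationError(f"unknown phase-error kind '{self.kind}'")
        if self.smooth_cutoff_frac <= 0:
            raise ConfigurationError("smooth_cutoff_frac must be positive")

    def phase_map(self, shot_key: tuple, shape: tuple, nav_band_ky: float | None = None) -> np.ndarray:
        """Phase map (radians) for one shot, shape ``(nx, ny)``.

        ``nav_band_ky`` is the navigator's maximum resolvable ky frequency
        in full-grid index units; required for ``smooth`` fields.
        """
        nx, ny = shape
        if self.kind == "none":
            return np.zeros((nx, ny))
        rng = np.random.default_rng((int(self.seed), 7919) + tuple(int(k) for k in shot_key))
        if self.kind == "constant":
            return np.full((nx, ny), rng.uniform(*self.constant_range))
        if self.kind == "linear":
            c = rng.uniform(*self.constant_range)
            gx = rng.uniform(*self.gradient_range)
            gy = rng.uniform(*self.gradient_range)
            x = (np.arange(nx) - nx // 2) / nx
            y = (np.arange(ny) - ny // 2) / ny
            return c + gx * x[:, None] + gy * y[None, :]
        # smooth: hard-truncated white noise in k-space
        if nav_band_ky is None:
            raise ValueError("smooth fields need the navigator bandwidth")
        ky_cut = self.smooth_cutoff_frac * nav_band_ky
        kx_cut = self.smooth_cutoff_frac * (nx / 2.0)
        noise = rng.standard_normal((nx, ny))
        spec = cfft2(noise)
        fx = np.arange(nx) - nx // 2
        fy = np.arange(ny) - ny // 2
        keep = (np.abs(fx)[:, None] <= kx_cut) & (np.abs(fy)[None, :] <= ky_cut)
        fieldc = np.fft.ifft2(np.fft.ifftshift(spec * keep))
        fld = np.real(np.fft.fftshift(fieldc))
        sd = fld.std()
        if sd > 0:
            fld = fld * (self.smooth_amplitude_rad / sd)
        return fld


@dataclass
class ShotRecord:
    """One shot's k-space: imaging lines, navigator, and ground truth.

    ``kspace`` has shape (n_coils, lines_per_shot, nx) with ascending ky
    rows; ``nav_kspace`` (n_coils, nav_lines, nx) holds the centre-most ky
    lines in linear order.  ``true_phase`` keeps the injected intershot
    phase map (nx, ny_full) for testing only — the reconstruction never
    reads it.
    """

    kz: int
    b_value: float
    average_index: int
    kspace: np.ndarray
    nav_kspace: np.ndarray
    true_phase: np.ndarray


@dataclass
class AcquisitionSet:
    """All shots of a multi-b acquisition plus shared metadata."""

    shots: list
    coil_sens: np.ndarray        # (n_coils, nx, ny_full)
    noise_sigma: float
    cfg: SequenceConfig
    fov_phase_fraction: float
    meta: dict = field(default_factory=dict)

    @property
    def step(self) -> int:
        """Full-grid ky lines per reduced-matrix ky step."""
        return int(self.meta.get("step", 1))

    def shots_for(self, b: float, average_index: int | None = None) -> list:
        out = [s for s in self.shots if s.b_value == b]
        if average_index is not None:
            out = [s for s in out if s.average_index == average_index]
        return out


def make_coil_sens(n_coils: int, grid_shape: tuple, seed: int = 0) -> np.ndarray:
    """Smooth synthetic coil sensitivity maps, (n_coils, nx, ny).

    Gaussian lobes centred on a ring around the object with a gentle
    per-coil linear phase; deterministic for a given seed.  A single coil
    gives a unit map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be at least 1")
    nx, ny = grid_shape[0], grid_shape[1]
    if n_coils == 1:
        return np.ones((1, nx, ny), dtype=complex)
    rng = np.random.default_rng((int(seed), 51721))
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    r_ring = 0.6 * max(nx, ny) / 2.0
    sigma = 0.6 * min(nx, ny)
    maps = np.empty((n_coils, nx, ny), dtype=complex)
    for c in range(n_coils):
        ang = 2.0 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        cx = nx / 2.0 + r_ring * np.cos(ang)
        cy = ny / 2.0 + r_ring * np.sin(ang)
        mag = np.exp(-(((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2)))
        px, py = rng.uniform(-np.pi, np.pi, size=2)
        phase = px * (x - nx / 2.0) / nx + py * (y - ny / 2.0) / ny + rng.uniform(0, 2 * np.pi)
        maps[c] = mag * np.exp(1j * phase)
    return maps


def encode_partition(obj: np.ndarray, kz_row: int) -> np.ndarray:
    """Partition-encode a volume: centred DFT along z, one kz row.

    ``obj`` has shape (..., nx, ny, nz); returns (..., nx, ny).  Row
    ``nz // 2`` is DC, i.e. a plain projection over the slab — which is
    exactly what the navigator (no partition encoding) measures.
    """
    nz = obj.shape[-1]
    kappa = kz_row - nz // 2
    w = np.exp(-2j * np.pi * kappa * (np.arange(nz) - nz // 2) / nz)
    return obj @ w


def _sample_line(plane: np.ndarray, col_full: int) -> np.ndarray:
    """One ky line (all kx) of the centred 2D DFT of (..., nx, ny) planes."""
    return cfft2(plane, axes=(-2, -1))[..., col_full]


def simulate_acquisition(
    tissue: TissueVolume,
    cfg: SequenceConfig,
    coil_sens: np.ndarray | None = None,
    phase_model: PhaseErrorModel | None = None,
    noise_sigma: float = 0.0,
    fov_phase_fraction: float = 1.0,
    profile_mode: str = "ideal",
    seed: int = 0,
    shot_order=None,
) -> AcquisitionSet:
    """Simulate the full multi-shot, multi-b, multi-average acquisition.

    For every (b, average, partition) shot: steady-state longitudinal
    magnetization → diffusion preparation with that shot's phase map →
    FLASH train sampling the centric ky lines of the reduced matrix →
    navigator lines from the further-attenuated stored magnetization.
    The object is weighted by the excitation profile and per-coil
    sensitivities before encoding.  Complex white Gaussian noise with
    standard deviation ``noise_sigma`` relative to the DC magnitude of the
    b=0 object is added per k-space sample.

    If the tissue grid's ny is an integer multiple ``step`` of
    ``lines_per_shot``, ky is sampled at ``step`` times coarser spacing —
    i.e. on a phase FOV reduced by ``1 / step`` — which aliases any signal
    the excitation profile leaves outside that FOV.

    ``shot_order`` optionally permutes the simulation order of the shots;
    the result is independent of it because every shot starts from the
    same (b-independent) steady state and all randomness is keyed by the
    shot's identity.
    """
    nx, ny_full, nz = tissue.grid_shape
    if nz != cfg.n_partitions:
        raise ConfigurationError(
            f"tissue nz={nz} must equal cfg.n_partitions={cfg.n_partitions}"
        )
    if ny_full % cfg.lines_per_shot != 0:
        raise ConfigurationError(
            f"tissue ny={ny_full} must be a multiple of lines_per_shot={cfg.lines_per_shot}"
        )
    step = ny_full // cfg.lines_per_shot
    ny_red = cfg.lines_per_shot
    if not isinstance(seed, (int, np.integer)):
        raise ValueError("seed must be an integer")

    if coil_sens is None:
        coil_sens = make_coil_sens(1, (nx, ny_full))
    coil_sens = np.asarray(coil_sens, dtype=complex)
    if coil_sens.shape[1:] != (nx, ny_full):
        raise ConfigurationError("coil sensitivities do not match the in-plane grid")
    if phase_model is None:
        phase_model = PhaseErrorModel(kind="none")

    profile = reduced_fov_profile(ny_full, fov_phase_fraction, profile_mode)
    if step > 1:
        inner = reduced_fov_profile(ny_full, 1.0 / step, "ideal") > 0
        outside = (profile * tissue.pd.sum(axis=(0, 2))) * (~inner)
        if np.abs(outside).sum() > 1e-12 * max(np.abs(tissue.pd).sum(), 1.0):
            warnings.warn("object energy outside the reduced phase FOV will alias")

    alpha = cfg.flip_rad
    e_te = np.exp(-cfg.te_readout_ms / tissue.t2_ms)
    dmap = np.cos(alpha) * np.exp(-cfg.echo_spacing_ms / tissue.t1_ms)
    ky_offsets = centric_order(ny_red)
    nav_offsets = np.arange(cfg.nav_lines) - cfg.nav_lines // 2
    nav_band_ky = cfg.nav_lines * step / 2.0

    # Noise reference: DC magnitude of the (profile- and coil-weighted)
    # b = 0 object at kz = DC.
    ss = steady_state_mz(tissue, cfg, b=0.0)
    prep0 = prep_amplitude(ss, tissue, 0.0, 0.0, cfg)
    sig0 = np.sin(alpha) * prep0.amplitude * e_te
    w0 = profile[None, None, :, None] * coil_sens[:, :, :, None] * sig0[None]
    dc_ref = np.abs(w0.sum(axis=(1, 2, 3))).max()
    sigma_abs = noise_sigma * dc_ref

    keys = [
        (bi, avg, kz)
        for bi, b in enumerate(cfg.b_values_s_per_mm2)
        for avg in range(cfg.averages[bi])
        for kz in range(nz)
    ]
    order = range(len(keys)) if shot_order is None else list(shot_order)
    records: dict[int, ShotRecord] = {}

    for idx in order:
        bi, avg, kz = keys[idx]
        b = cfg.b_values_s_per_mm2[bi]
        theta = phase_model.phase_map((bi, avg, kz), (nx, ny_full), nav_band_ky=nav_band_ky)
        prep = prep_amplitude(ss, tissue, b, theta, cfg)
        sig = np.sin(alpha) * prep.amplitude * e_te
        cur = profile[None, None, :, None] * coil_sens[:, :, :, None] * sig[None]

        n_coils = coil_sens.shape[0]
        kspace = np.empty((n_coils, ny_red, nx), dtype=complex)
        for n, off in enumerate(ky_offsets):
            if n > 0:
                cur = cur * dmap
            plane = encode_partition(cur, kz)          # (nc, nx, ny_full)
            line = _sample_line(plane, ny_full // 2 + off * step)
            kspace[:, ny_red // 2 + off, :] = line

        nav = np.empty((n_coils, cfg.nav_lines, nx), dtype=complex)
        for m, off in enumerate(nav_offsets):
            cur = cur * dmap                           # train decay continues
            plane = encode_partition(cur, nz // 2)     # kz = 0: slab projection
            nav[:, m, :] = _sample_line(plane, ny_full // 2 + off * step)

        if sigma_abs > 0:
            rng = np.random.default_rng((int(seed), 104729, bi, avg, kz))
            kspace = kspace + sigma_abs * (
                rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
            )
            nav = nav + sigma_abs * (
                rng.standard_normal(nav.shape) + 1j * rng.standard_normal(nav.shape)
            )

        records[idx] = ShotRecord(
            kz=kz, b_value=b, average_index=avg,
            kspace=kspace, nav_kspace=nav, true_phase=theta,
        )

    shots = [records[i] for i in range(len(keys))]
    return AcquisitionSet(
        shots=shots,
        coil_sens=coil_sens,
        noise_sigma=noise_sigma,
        cfg=cfg,
        fov_phase_fraction=fov_phase_fraction,
        meta={"step": step, "grid_shape": tissue.grid_shape, "seed": int(seed),
              "profile_mode": profile_mode},
    )


# ---- HDF5 serialization ----------------------------------------------------


def save_acquisition(acq: AcquisitionSet, path) -> None:
    """Write an AcquisitionSet to HDF5 (groups /shots/<i>, /coil_sens, /config)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["noise_sigma"] = acq.noise_sigma
        f.attrs["fov_phase_fraction"] = acq.fov_phase_fraction
        for k, v in acq.meta.items():
            f.attrs[f"meta_{k}"] = v
        f.create_dataset("coil_sens", data=acq.coil_sens)
        f.create_dataset("config", data=acq.cfg.to_yaml())
        shots = f.create_group("shots")
        gt = f.create_group("ground_truth/phase_maps")
        for i, s in enumerate(acq.shots):
            g = shots.create_group(str(i))
            g.create_dataset("kspace", data=s.kspace)
            g.create_dataset("nav", data=s.nav_kspace)
            g.attrs["kz"] = s.kz
            g.attrs["b_value"] = s.b_value
            g.attrs["average_index"] = s.average_index
            gt.create_dataset(str(i), data=s.true_phase)


def load_acquisition(path) -> AcquisitionSet:
    with h5py.File(path, "r") as f:
        cfg = SequenceConfig.from_yaml(f["config"][()].decode())
        coil_sens = f["coil_sens"][()]
        meta = {
            k[len("meta_"):]: (tuple(v) if isinstance(v, np.ndarray) else v)
            for k, v in f.attrs.items() if k.startswith("meta_")
        }
        shots = []
        indices = sorted(f["shots"], key=int)
        for i in indices:
            g = f["shots"][i]
            shots.append(
                ShotRecord(
                    kz=int(g.attrs["kz"]),
                    b_value=float(g.attrs["b_value"]),
                    average_index=int(g.attrs["average_index"]),
                    kspace=g["kspace"][()],
                    nav_kspace=g["nav"][()],
                    true_phase=f["ground_truth/phase_maps"][i][()],
                )
            )
        return AcquisitionSet(
            shots=shots,
            coil_sens=coil_sens,
            noise_sigma=float(f.attrs["noise_sigma"]),
            cfg=cfg,
            fov_phase_fraction=float(f.attrs["fov_phase_fraction"]),
            meta=meta,
        )
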