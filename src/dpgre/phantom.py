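"""Synthetic quantitative tissue volumes.

Two digital objects are provided as ground truth for the simulator: a
six-vial diffusion phantom (cylindrical vials of polymer solution in a
water bath, each with a known ADC) and a simplified sagittal cervical-spine
object (cord strip, surrounding CSF, vertebral bodies).

Array convention, used package-wide: volumes are indexed ``[x, y, z]`` with
x = readout, y = phase encode, z = partition encode; index ``(0, 0, 0)`` is
a corner and voxel centres sit on integer indices.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage

from .errors import ConfigurationError

#: Free-water diffusivity bound (body temperature, with margin), mm^2/s.
ADC_MAX = 3.5e-3


@dataclass
class TissueVolume:
    """Per-voxel quantitative maps on a 3D grid.

    Attributes
    ----------
    grid_shape : tuple of int
        ``(nx, ny, nz)``.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm.
    pd, t1_ms, t2_ms, adc_mm2_per_s : ndarray
        Proton density (arbitrary units), relaxation times (ms) and apparent
        diffusion coefficient (mm^2/s), one value per voxel.
    labels : ndarray of int
        0 = background, k = vial / tissue class k.
    """

    grid_shape: tuple
    voxel_size_mm: tuple
    pd: np.ndarray
    t1_ms: np.ndarray
    t2_ms: np.ndarray
    adc_mm2_per_s: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.grid_shape)
        self.grid_shape = shape
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        for name in ("pd", "t1_ms", "t2_ms", "adc_mm2_per_s", "labels"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ConfigurationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)
        if np.any(self.pd < 0):
            raise ValueError("proton density must be nonnegative")
        if np.any(self.t1_ms <= 0) or np.any(self.t2_ms <= 0):
            raise ValueError("relaxation times must be positive")
        tissue = self.pd > 0
        if np.any(self.t2_ms[tissue] > self.t1_ms[tissue]):
            raise ValueError("t2 must not exceed t1 where pd > 0")
        if np.any(self.adc_mm2_per_s < 0) or np.any(self.adc_mm2_per_s > ADC_MAX):
            raise ValueError(f"ADC values must lie in [0, {ADC_MAX}] mm^2/s")

    @property
    def fov_mm(self) -> tuple:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_mm))

    def label_mean_adc(self, label: int) -> float:
        """Ground-truth mean ADC over one label region."""
        mask = self.labels == label
        if not mask.any():
            raise ValueError(f"label {label} has no voxels")
        return float(self.adc_mm2_per_s[mask].mean())

    # ---- NIfTI I/O ------------------------------------------------------

    def save(self, out_dir) -> dict:
        """Write one NIfTI file per map; returns {map name: path}."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        paths = {}
        for name, arr, dtype in (
            ("pd", self.pd, np.float64),
            ("t1", self.t1_ms, np.float64),
            ("t2", self.t2_ms, np.float64),
            ("adc", self.adc_mm2_per_s, np.float64),
            ("labels", self.labels, np.int16),
        ):
            path = out_dir / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr.astype(dtype), affine), path)
            paths[name] = path
        return paths

    @classmethod
    def load(cls, in_dir) -> "TissueVolume":
        in_dir = Path(in_dir)
        maps = {}
        for name in ("pd", "t1", "t2", "adc", "labels"):
            img = nib.load(in_dir / f"{name}.nii.gz")
            maps[name] = np.asarray(img.dataobj)
        voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            grid_shape=maps["pd"].shape,
            voxel_size_mm=voxel,
            pd=maps["pd"],
            t1_ms=maps["t1"],
            t2_ms=maps["t2"],
            adc_mm2_per_s=maps["adc"],
            labels=maps["labels"].astype(int),
        )


@dataclass
class RoiMask:
    """Named boolean region of interest on the same grid as its volume."""

    mask: np.ndarray
    name: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI '{self.name}' is empty")

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), np.eye(4)), path)


def _disc(nx: int, ny: int, cx: float, cy: float, radius: float) -> np.ndarray:
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (x - cx) ** 2 + (y - cy) ** 2 <= radius**2


def make_vial_phantom(
    n_vials: int,
    adc_values,
    grid_shape=(64, 64, 8),
    voxel_size_mm=(2.1, 2.1, 4.0),
    background_adc: float = 2.0e-3,
    vial_radius_frac: float = 0.10,
    ring_radius_frac: float = 0.28,
    container_radius_frac: float = 0.45,
    t1_vial_ms: float = 1000.0,
    t2_vial_ms: float = 500.0,
    t1_bath_ms: float = 3000.0,
    t2_bath_ms: float = 1500.0,
) -> TissueVolume:
    """Cylindrical-vial diffusion phantom.

    ``n_vials`` cylinders (radius ``vial_radius_frac`` of the smaller
    in-plane FOV) are placed on a hexagonal ring inside a circular water
    bath.  Each vial's ADC is exactly the requested value; the bath sits at
    ``background_adc``.  Construction is fully deterministic.
    """
    adc_values = [float(a) for a in adc_values]
    if n_vials != len(adc_values):
        raise ConfigurationError("n_vials must equal len(adc_values)")
    if any(a < 0 for a in adc_values) or background_adc < 0:
        raise ValueError("ADC values must be nonnegative")
    if any(a > ADC_MAX for a in adc_values) or background_adc > ADC_MAX:
        raise ValueError(f"ADC values must not exceed {ADC_MAX} mm^2/s")

    nx, ny, nz = grid_shape
    fov = min(nx, ny)  # in voxel units; radii are fractions of this extent
    r_vial = vial_radius_frac * fov
    r_ring = ring_radius_frac * fov
    r_cont = container_radius_frac * fov
    cx, cy = nx / 2.0, ny / 2.0

    # Hexagonal arrangement: vials evenly spaced on a ring (6 positions for
    # the standard phantom); verify the geometry before rasterizing.
    if n_vials > 1:
        gap = 2.0 * r_ring * np.sin(np.pi / n_vials)
        if gap < 2.0 * r_vial:
            raise ConfigurationError(
                f"{n_vials} vials of radius {r_vial:.1f} vox overlap on a ring "
                f"of radius {r_ring:.1f} vox"
            )
    if r_ring + r_vial > r_cont:
        raise ConfigurationError("vials do not fit inside the container")

    pd = np.zeros(grid_shape)
    t1 = np.full(grid_shape, 1000.0)
    t2 = np.full(grid_shape, 500.0)
    adc = np.zeros(grid_shape)
    labels = np.zeros(grid_shape, dtype=int)

    bath = _disc(nx, ny, cx, cy, r_cont)[..., None] & np.ones(nz, dtype=bool)
    pd[bath] = 1.0
    t1[bath] = t1_bath_ms
    t2[bath] = t2_bath_ms
    adc[bath] = background_adc

    for k, a in enumerate(adc_values, start=1):
        ang = 2.0 * np.pi * (k - 1) / max(n_vials, 1)
        vx = cx + r_ring * np.cos(ang)
        vy = cy + r_ring * np.sin(ang)
        vial = _disc(nx, ny, vx, vy, r_vial)[..., None] & np.ones(nz, dtype=bool)
        if not vial.any():
            raise ConfigurationError("grid too small to rasterize a vial")
        pd[vial] = 1.0
        t1[vial] = t1_vial_ms
        t2[vial] = t2_vial_ms
        adc[vial] = a
        labels[vial] = k

    return TissueVolume(grid_shape, voxel_size_mm, pd, t1, t2, adc, labels)


def vial_roi(volume: TissueVolume, label: int, margin_vox: int = 0) -> RoiMask:
    """ROI over one vial, optionally eroded in-plane by ``margin_vox``.

    Mimics manual ROI placement in phantom QA, which avoids vial edges to
    exclude partial-volume voxels.
    """
    mask = volume.labels == label
    if margin_vox > 0:
        structure = np.zeros((3, 3, 1), dtype=bool)
        structure[:, 1, 0] = structure[1, :, 0] = True
        mask = ndimage.binary_erosion(mask, structure=structure, iterations=margin_vox)
    return RoiMask(mask, name=f"vial_{label}")


# Cord phantom label values
CORD, CSF, VERTEBRA = 1, 2, 3


def make_cord_phantom(
    grid_shape=(64, 32, 8),
    voxel_size_mm=(2.1, 2.1, 4.0),
    cord_adc: float = 0.9e-3,
    csf_adc: float = 3.0e-3,
    vertebra_adc: float = 0.5e-3,
):
    """Simplified sagittal cervical-spine object with a cord ROI.

    The x axis runs head-foot (readout), y anterior-posterior (reduced
    phase-encode), z left-right (partitions).  A thin cord strip is
    surrounded by CSF; periodic vertebral-body blocks sit anterior to the
    canal with disc gaps.  Returns ``(TissueVolume, RoiMask)``; the ROI is
    a central segment strictly inside the cord.
    """
    nx, ny, nz = grid_shape
    if nx < 32 or ny < 16 or nz < 4:
        raise ConfigurationError("cord phantom needs a grid of at least (32, 16, 4)")

    pd = np.zeros(grid_shape)
    t1 = np.full(grid_shape, 1000.0)
    t2 = np.full(grid_shape, 80.0)
    adc = np.zeros(grid_shape)
    labels = np.zeros(grid_shape, dtype=int)

    yc = ny // 2
    cord_hw = max(1, ny // 16)          # cord half-width in y
    canal_hw = cord_hw + max(2, ny // 8)  # CSF-filled canal half-width
    zc = nz // 2
    z_sl = slice(max(0, zc - 2), min(nz, zc + 2))
    x_sl = slice(nx // 8, nx - nx // 8)

    canal = np.zeros(grid_shape, dtype=bool)
    canal[x_sl, yc - canal_hw : yc + canal_hw + 1, z_sl] = True
    pd[canal] = 1.0
    t1[canal] = 4000.0
    t2[canal] = 2000.0
    adc[canal] = csf_adc
    labels[canal] = CSF

    cord = np.zeros(grid_shape, dtype=bool)
    cord[x_sl, yc - cord_hw : yc + cord_hw + 1, z_sl] = True
    pd[cord] = 0.8
    t1[cord] = 1000.0
    t2[cord] = 75.0
    adc[cord] = cord_adc
    labels[cord] = CORD

    # Vertebral bodies: blocks anterior to the canal, with disc gaps.
    body_y = slice(max(0, yc - canal_hw - max(3, ny // 6)), yc - canal_hw - 1)
    period = max(8, nx // 6)
    for x0 in range(nx // 8, nx - nx // 8, period):
        x1 = min(x0 + period - 3, nx - nx // 8)
        block = np.zeros(grid_shape, dtype=bool)
        block[x0:x1, body_y, z_sl] = True
        pd[block] = 0.6
        t1[block] = 400.0
        t2[block] = 50.0
        adc[block] = vertebra_adc
        labels[block] = VERTEBRA

    roi = np.zeros(grid_shape, dtype=bool)
    roi[nx // 2 - nx // 8 : nx // 2 + nx // 8, yc - cord_hw : yc + cord_hw + 1, zc] = True
    roi &= labels == CORD

    volume = TissueVolume(grid_shape, voxel_size_mm, pd, t1, t2, adc, labels)
    return volume, RoiMask(roi, name="cord")
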