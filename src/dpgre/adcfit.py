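"""Two-point apparent-diffusion-coefficient mapping and phantom QA stats.

With only two b-values the mono-exponential model ``S_b = S_0 exp(-b ADC)``
has the exact solution ``ADC = ln(S_0 / S_b) / b``; no iterative fitting is
needed.  Voxels whose signal falls below a floor (fraction of the peak b=0
signal) are excluded from the log to keep background noise out of the map.
For phantom validation, measured per-vial means are regressed against the
reference values by ordinary least squares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import stats

from .errors import SignalError
from .phantom import RoiMask

__all__ = ["ADCResult", "fit_adc", "roi_mean_adc", "label_stats", "reference_regression"]


@dataclass
class ADCResult:
    """Per-voxel ADC map with its validity mask and optional summaries."""

    adc_map: np.ndarray              # mm^2/s
    valid_mask: np.ndarray
    b_value: float
    roi_stats: dict = field(default_factory=dict)
    fit_stats: dict | None = None

    def save(self, out_dir, voxel_size_mm=(1.0, 1.0, 1.0)) -> dict:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(voxel_size_mm) + [1.0])
        paths = {}
        paths["adc"] = out_dir / "adc.nii.gz"
        nib.save(nib.Nifti1Image(self.adc_map.astype(np.float64), affine), paths["adc"])
        paths["valid"] = out_dir / "adc_valid.nii.gz"
        nib.save(nib.Nifti1Image(self.valid_mask.astype(np.uint8), affine), paths["valid"])
        stats_blob = {"b_value": self.b_value, "roi_stats": self.roi_stats,
                      "fit_stats": self.fit_stats}
        paths["stats"] = out_dir / "adc_stats.json"
        paths["stats"].write_text(json.dumps(stats_blob, indent=2))
        return paths


def fit_adc(mag_b0: np.ndarray, mag_b: np.ndarray, b: float, floor: float = 0.01) -> ADCResult:
    """Two-point log-ratio ADC map.

    ``adc = ln(S0 / Sb) / b`` wherever both signals exceed
    ``floor * max(S0)``; elsewhere the voxel is marked invalid and set to
    zero.  Negative estimates (possible under noise) are retained, not
    clamped.
    """
    if b <= 0:
        raise ValueError("b must be positive for a two-point fit")
    s0 = np.asarray(mag_b0, dtype=float)
    sb = np.asarray(mag_b, dtype=float)
    if s0.shape != sb.shape:
        raise ValueError("b0 and diffusion-weighted maps must share a shape")
    if np.any(s0 < 0) or np.any(sb < 0):
        raise ValueError("magnitude inputs must be nonnegative")
    threshold = floor * s0.max()
    valid = (s0 > threshold) & (sb > threshold)
    adc = np.zeros_like(s0)
    adc[valid] = np.log(s0[valid] / sb[valid]) / b
    return ADCResult(adc_map=adc, valid_mask=valid, b_value=float(b))


def roi_mean_adc(result: ADCResult, roi: RoiMask) -> tuple:
    """Mean and SD of the ADC over the valid voxels of one ROI."""
    sel = roi.mask & result.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise SignalError(f"ROI '{roi.name}' has no valid ADC voxels")
    vals = result.adc_map[sel]
    mean, sd = float(vals.mean()), float(vals.std(ddof=0))
    result.roi_stats[roi.name] = {"mean": mean, "sd": sd, "n_voxels": n}
    return mean, sd


def label_stats(result: ADCResult, labels: np.ndarray, margin_vox: int = 0) -> dict:
    """Per-label ROI statistics (labels > 0), via :func:`roi_mean_adc`.

    ``margin_vox`` erodes each label in-plane before averaging, mimicking
    manual ROI placement that avoids region edges.
    """
    from scipy import ndimage

    structure = np.zeros((3, 3, 1), dtype=bool)
    structure[:, 1, 0] = structure[1, :, 0] = True
    out = {}
    for lab in sorted(int(l) for l in np.unique(labels) if l > 0):
        mask = labels == lab
        if margin_vox > 0:
            mask = ndimage.binary_erosion(mask, structure=structure, iterations=margin_vox)
        roi = RoiMask(mask, name=f"vial_{lab}")
        mean, sd = roi_mean_adc(result, roi)
        out[lab] = {"mean": mean, "sd": sd, "n_voxels": result.roi_stats[roi.name]["n_voxels"]}
    return out


def reference_regression(measured_per_vial, reference_per_vial) -> dict:
    """OLS of measured vs reference per-vial ADC.

    Returns slope, intercept (mm^2/s), R^2 and the RMS residual (mm^2/s) of
    the fit — the standard phantom-accuracy summary.
    """
    meas = np.asarray(measured_per_vial, dtype=float)
    ref = np.asarray(reference_per_vial, dtype=float)
    if meas.shape != ref.shape or meas.ndim != 1:
        raise ValueError("measured and reference must be 1D with equal length")
    if meas.size < 3:
        raise ValueError("need at least 3 vials for a linear fit")
    fit = stats.linregress(ref, meas)
    predicted = fit.intercept + fit.slope * ref
    rmse = float(np.sqrt(np.mean((meas - predicted) ** 2)))
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "rmse": rmse,
    }
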