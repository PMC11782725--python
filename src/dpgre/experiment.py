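"""Reproducible experiment driver: phantom → simulate → recon → ADC.

A single YAML document configures the whole chain.  One global seed fans
out to per-stage child seeds through a fixed counter scheme, so any stage
can be re-run in isolation and the chain is bit-reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .acquire import PhaseErrorModel, make_coil_sens, save_acquisition, simulate_acquisition
from .adcfit import fit_adc, label_stats, reference_regression, roi_mean_adc
from .errors import ConfigurationError
from .phantom import RoiMask, make_cord_phantom, make_vial_phantom
from .recon import reconstruct, save_volume
from .seqsim import SequenceConfig

__all__ = ["ExperimentConfig", "validate_config", "run_experiment", "default_config"]

# Stage offsets for the counter-based child-seed scheme.
_STAGE_SEEDS = {"phantom": 1, "acquire": 2, "noise": 3}
_SEED_MOD = 2**31 - 1


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000003 + _STAGE_SEEDS[stage]) % _SEED_MOD


@dataclass
class ExperimentConfig:
    """Typed, validated configuration for one end-to-end experiment."""

    phantom: dict = field(default_factory=lambda: {"type": "vials"})
    sequence: SequenceConfig = field(default_factory=SequenceConfig)
    acquisition: dict = field(default_factory=dict)
    recon: dict = field(default_factory=dict)
    adc: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        ptype = self.phantom.get("type", "vials")
        if ptype not in ("vials", "cord"):
            raise ConfigurationError(f"phantom.type must be 'vials' or 'cord', got '{ptype}'")
        b_fit = float(self.adc.get("b", max(self.sequence.b_values_s_per_mm2)))
        if b_fit not in self.sequence.b_values_s_per_mm2:
            raise ConfigurationError(
                f"adc.b={b_fit} is not among the sequence b-values"
            )
        if b_fit == 0:
            raise ConfigurationError("adc.b must be a nonzero b-value")
        self.adc["b"] = b_fit
        kind = self.acquisition.get("phase_model", "none")
        if kind not in ("none", "constant", "linear", "smooth"):
            raise ConfigurationError(f"unknown phase model '{kind}'")
        noisy = float(self.acquisition.get("noise_sigma", 0.0)) > 0 or kind != "none"
        if noisy and self.seed is None:
            raise ConfigurationError("a seed is required when noise or phase errors are enabled")


def default_config() -> dict:
    """Dictionary form of the bundled protocol defaults."""
    cfg = ExperimentConfig()
    d = dataclasses.asdict(cfg)
    d["sequence"] = yaml.safe_load(cfg.sequence.to_yaml())
    return d


def validate_config(raw) -> ExperimentConfig:
    """Parse a YAML/JSON document (text, path or dict) into an ExperimentConfig.

    Missing keys take the protocol defaults; unknown keys produce a
    warning; cross-field violations raise with the offending field path.
    """
    if isinstance(raw, Path) or (
        isinstance(raw, str) and raw and "\n" not in raw and Path(raw).is_file()
    ):
        raw = Path(raw).read_text()
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    known = {"phantom", "sequence", "acquisition", "recon", "adc", "seed"}
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config sections: {sorted(unknown)}")
    seq_raw = raw.get("sequence", {}) or {}
    sequence = SequenceConfig.from_dict(seq_raw)
    return ExperimentConfig(
        phantom=dict(raw.get("phantom", {"type": "vials"})),
        sequence=sequence,
        acquisition=dict(raw.get("acquisition", {})),
        recon=dict(raw.get("recon", {})),
        adc=dict(raw.get("adc", {})),
        seed=int(raw.get("seed", 0)),
    )


def _build_phantom(cfg: ExperimentConfig):
    p = cfg.phantom
    seq = cfg.sequence
    if p.get("type", "vials") == "vials":
        adc_values = p.get(
            "adc_values", [0.4e-3, 0.6e-3, 0.8e-3, 1.1e-3, 1.5e-3, 2.0e-3]
        )
        grid = tuple(p.get("grid_shape", (64, seq.lines_per_shot, seq.n_partitions)))
        vol = make_vial_phantom(
            n_vials=len(adc_values),
            adc_values=adc_values,
            grid_shape=grid,
            voxel_size_mm=tuple(p.get("voxel_size_mm", (2.1, 2.1, 4.0))),
            background_adc=float(p.get("background_adc", 2.0e-3)),
        )
        return vol, None
    grid = tuple(p.get("grid_shape", (64, seq.lines_per_shot, seq.n_partitions)))
    return make_cord_phantom(
        grid_shape=grid,
        voxel_size_mm=tuple(p.get("voxel_size_mm", (2.1, 2.1, 4.0))),
        cord_adc=float(p.get("cord_adc", 0.9e-3)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(cfg: ExperimentConfig, out_dir) -> dict:
    """Execute the full chain and write a manifest of everything produced."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "phantom"
    outputs = {}
    try:
        tissue, roi = _build_phantom(cfg)
        ph_paths = tissue.save(out_dir / "phantom")
        outputs.update({f"phantom/{k}": str(v) for k, v in ph_paths.items()})
        if roi is not None:
            roi_path = out_dir / "phantom" / "roi.nii.gz"
            roi.save(roi_path)
            outputs["phantom/roi"] = str(roi_path)

        stage = "simulate"
        acq_cfg = cfg.acquisition
        n_coils = int(acq_cfg.get("n_coils", 1))
        sens = make_coil_sens(
            n_coils, tissue.grid_shape[:2], seed=stage_seed(cfg.seed, "phantom")
        )
        model = PhaseErrorModel(
            kind=acq_cfg.get("phase_model", "none"),
            smooth_cutoff_frac=float(acq_cfg.get("smooth_cutoff_frac", 0.5)),
            smooth_amplitude_rad=float(acq_cfg.get("smooth_amplitude_rad", 0.3)),
            seed=stage_seed(cfg.seed, "acquire"),
        )
        acq = simulate_acquisition(
            tissue, cfg.sequence,
            coil_sens=sens,
            phase_model=model,
            noise_sigma=float(acq_cfg.get("noise_sigma", 0.0)),
            fov_phase_fraction=float(acq_cfg.get("fov_phase_fraction", 1.0)),
            profile_mode=acq_cfg.get("profile_mode", "ideal"),
            seed=stage_seed(cfg.seed, "noise"),
        )
        h5_path = out_dir / "kspace.h5"
        save_acquisition(acq, h5_path)
        outputs["kspace"] = str(h5_path)

        stage = "recon"
        volumes = reconstruct(
            acq,
            correct=bool(cfg.recon.get("correction", True)),
            epsilon=float(cfg.recon.get("epsilon", 0.05)),
            coil_method=cfg.recon.get("coil_combine", "matched"),
            averaging=cfg.recon.get("averaging", "complex"),
        )
        for b, vol in volumes.items():
            paths = save_volume(vol, out_dir / "recon", f"b{int(b)}", tissue.voxel_size_mm)
            outputs.update({f"recon/b{int(b)}_{k}": str(v) for k, v in paths.items()})

        stage = "adc"
        b_fit = cfg.adc["b"]
        result = fit_adc(
            volumes[0.0].magnitude, volumes[b_fit].magnitude, b_fit,
            floor=float(cfg.adc.get("floor", 0.01)),
        )
        if roi is not None:
            roi_crop = _crop_roi(roi, result.adc_map.shape)
            roi_mean_adc(result, roi_crop)
        else:
            labels = _crop_labels(tissue.labels, result.adc_map.shape)
            per_vial = label_stats(result, labels,
                                   margin_vox=int(cfg.adc.get("roi_margin_vox", 1)))
            refs = [tissue.label_mean_adc(lab) for lab in per_vial]
            if len(per_vial) >= 3:
                result.fit_stats = reference_regression(
                    [v["mean"] for v in per_vial.values()], refs
                )
        adc_paths = result.save(out_dir / "adc", tissue.voxel_size_mm)
        outputs.update({f"adc/{k}": str(v) for k, v in adc_paths.items()})
    except Exception as exc:  # annotate with the failed stage, keep partial outputs
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_SEEDS},
        "config": {
            "phantom": cfg.phantom,
            "sequence": yaml.safe_load(cfg.sequence.to_yaml()),
            "acquisition": cfg.acquisition,
            "recon": cfg.recon,
            "adc": cfg.adc,
        },
        "outputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in outputs.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _crop_roi(roi: RoiMask, target_shape) -> RoiMask:
    return RoiMask(_crop_labels(roi.mask, target_shape), name=roi.name)


def _crop_labels(arr: np.ndarray, target_shape):
    """Crop the central reduced phase FOV out of a full-grid array."""
    if arr.shape == tuple(target_shape):
        return arr
    ny_full, ny_red = arr.shape[1], target_shape[1]
    start = ny_full // 2 - ny_red // 2
    return arr[:, start : start + ny_red, :]
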