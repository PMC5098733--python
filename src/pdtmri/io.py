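"""File I/O: NIfTI volumes with JSON sidecars, geometry matching, configuration.

Conventions: image stacks are written as 4D NIfTI-1 with the contrast
dimension on the 4th axis and a sidecar JSON naming the contrast kind and
its coordinate values; parameter maps are 3D NIfTI-1 with the unit recorded
in the header description and invalid voxels stored as NaN (a companion
``*_mask`` volume is written for integer-only consumers). Voxel indices are
0-based, slice positions are voxel centers, and masks are co-registered by
index — co-acquired geometries, no resampling.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import ContrastAxis, ImageStack, ParameterMap
from .dce import AIFModel
from .errors import ConfigError, FormatError, GeometryError
from .phantom import TreatmentEffectSpec
from .protocol import AcquisitionProtocol, VoxelGrid

__all__ = [
    "read_stack",
    "write_stack",
    "read_map",
    "write_map",
    "match_geometry",
    "PipelineConfig",
    "load_config",
    "write_run_log",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    return np.diag([grid.dx_mm, grid.dy_mm, grid.slice_pitch_mm, 1.0])


def _grid_from_header(img) -> VoxelGrid:
    nx, ny, nz = img.shape[:3]
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid(
        nx=nx, ny=ny, nz=nz,
        dx_mm=float(zooms[0]), dy_mm=float(zooms[1]),
        slice_thickness_mm=float(zooms[2]), slice_gap_mm=0.0,
    )


def write_stack(stack: ImageStack, path, sidecar_path=None) -> Path:
    """4D NIfTI-1 plus a sidecar JSON with the contrast-axis coordinates."""
    path = Path(path)
    if sidecar_path is None:
        sidecar_path = path.with_name(path.name.split(".")[0] + ".json")
    img = nib.Nifti1Image(stack.frames.astype(np.float64), _affine(stack.grid))
    img.header.set_zooms(
        (stack.grid.dx_mm, stack.grid.dy_mm, stack.grid.slice_pitch_mm, 1.0)
    )
    nib.save(img, str(path))
    sidecar = {
        "contrast": stack.contrast_axis.kind,
        "values": stack.contrast_axis.values.tolist(),
        "slice_thickness_mm": stack.grid.slice_thickness_mm,
        "slice_gap_mm": stack.grid.slice_gap_mm,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path, sidecar_path) -> ImageStack:
    """Read a 3D/4D NIfTI with its sidecar; frame/coordinate counts must agree."""
    img = nib.load(str(path))
    if img.ndim not in (3, 4):
        raise FormatError(f"expected a 3D or 4D volume, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    sidecar = json.loads(Path(sidecar_path).read_text())
    values = np.asarray(sidecar["values"], dtype=float)
    n_coords = values.shape[0]
    if data.shape[3] != n_coords:
        raise FormatError(
            f"volume has {data.shape[3]} frames but sidecar lists {n_coords} coordinates"
        )
    grid = _grid_from_header(img)
    if "slice_thickness_mm" in sidecar:
        grid = VoxelGrid(
            grid.nx, grid.ny, grid.nz, grid.dx_mm, grid.dy_mm,
            float(sidecar["slice_thickness_mm"]), float(sidecar.get("slice_gap_mm", 0.0)),
        )
    return ImageStack(grid, data, ContrastAxis(sidecar["contrast"], values))


def write_map(pmap: ParameterMap, path, mask_path=None) -> Path:
    """3D NIfTI-1 with unit in the header description; invalid voxels as NaN."""
    path = Path(path)
    img = nib.Nifti1Image(pmap.values.astype(np.float64), _affine(pmap.grid))
    img.header.set_zooms((pmap.grid.dx_mm, pmap.grid.dy_mm, pmap.grid.slice_pitch_mm))
    img.header["descrip"] = pmap.unit.encode()[:79]
    nib.save(img, str(path))
    if mask_path is None:
        mask_path = path.with_name(path.name.split(".")[0] + "_mask.nii.gz")
    mask_img = nib.Nifti1Image(pmap.valid_mask.astype(np.uint8), _affine(pmap.grid))
    nib.save(mask_img, str(mask_path))
    return path


def read_map(path, slice_gap_mm: float = 0.0) -> ParameterMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    grid = _grid_from_header(img)
    if slice_gap_mm:
        grid = VoxelGrid(
            grid.nx, grid.ny, grid.nz, grid.dx_mm, grid.dy_mm,
            grid.slice_thickness_mm - slice_gap_mm, slice_gap_mm,
        )
    unit = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "dimensionless"
    return ParameterMap(grid, data, unit, np.isfinite(data))


def match_geometry(stack: ImageStack, target: VoxelGrid) -> ImageStack:
    """Down-sample a fine-sliced 3D acquisition onto a 2D multi-slice grid.

    Groups of thin source slices whose centers fall inside each target
    slice's pitch window are averaged; in-plane dimensions are unchanged.
    Raises if any target window contains no source slice.
    """
    src = stack.grid
    if (src.nx, src.ny) != (target.nx, target.ny):
        raise GeometryError("in-plane dimensions must match")
    src_pitch, tgt_pitch = src.slice_pitch_mm, target.slice_pitch_mm
    centers = (np.arange(src.nz) + 0.5) * src_pitch
    out = np.empty((target.nx, target.ny, target.nz, stack.n_frames))
    for k in range(target.nz):
        lo, hi = k * tgt_pitch, (k + 1) * tgt_pitch
        sel = (centers >= lo) & (centers < hi)
        if not sel.any():
            raise GeometryError(
                f"target slice {k} window [{lo:.2f}, {hi:.2f}) mm contains no source slice"
            )
        out[:, :, k] = stack.frames[:, :, sel].mean(axis=2)
    return ImageStack(target, out, stack.contrast_axis)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs: protocol, AIF, QC thresholds, seeds."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    aif: AIFModel = field(default_factory=AIFModel)
    r2_threshold: float = 0.80
    ttp_max_s: float = 800.0
    enhancement_sd_multiplier: float = 2.0
    min_included_voxels: int = 10
    seed: int = 0
    snr: float | None = 50.0
    grid: VoxelGrid = field(default_factory=lambda: VoxelGrid(32, 32, 8, 40 / 32, 40 / 32))
    treatment_effects: dict[str, TreatmentEffectSpec] = field(default_factory=dict)
    out_dir: str = "."


_SCHEMA: dict[str, tuple[type, ...]] = {
    "protocol": (dict,),
    "aif": (dict,),
    "grid": (dict,),
    "qc": (dict,),
    "treatment_effects": (dict,),
    "seed": (int,),
    "snr": (int, float, type(None)),
    "out_dir": (str,),
}
_QC_KEYS = {"r2_threshold", "ttp_max_s", "enhancement_sd_multiplier", "min_included_voxels"}


def load_config(path) -> PipelineConfig:
    """Parse and structurally validate a YAML pipeline configuration.

    Unknown top-level keys, wrong value types, and invariant violations
    (delegated to the domain types' own validation) raise ConfigError.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key, types in _SCHEMA.items():
        if key in raw and not isinstance(raw[key], types):
            raise ConfigError(f"config key {key!r} has wrong type {type(raw[key]).__name__}")

    kwargs: dict = {}
    try:
        if "protocol" in raw:
            kwargs["protocol"] = AcquisitionProtocol(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["protocol"].items()
            })
        if "aif" in raw:
            kwargs["aif"] = AIFModel(**raw["aif"])
        if "grid" in raw:
            kwargs["grid"] = VoxelGrid(**raw["grid"])
        if "treatment_effects" in raw:
            kwargs["treatment_effects"] = {
                tp: TreatmentEffectSpec(timepoint=tp, **spec)
                for tp, spec in raw["treatment_effects"].items()
            }
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    qc = raw.get("qc", {})
    bad_qc = set(qc) - _QC_KEYS
    if bad_qc:
        raise ConfigError(f"unknown qc key(s): {sorted(bad_qc)}")
    kwargs.update(qc)
    for key in ("seed", "snr", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    return PipelineConfig(**kwargs)


def write_run_log(out_dir, command: str, seed: int, config: PipelineConfig | None = None,
                  inputs: dict | None = None) -> Path:
    """Structured reproducibility log: inputs, config hash, seed, versions."""
    import nibabel
    import scipy

    from . import __version__

    payload = {
        "command": command,
        "seed": seed,
        "inputs": inputs or {},
        "versions": {
            "pdtmri": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    if config is not None:
        cfg = json.dumps(asdict(config), sort_keys=True, default=str)
        payload["config"] = json.loads(cfg)
        payload["config_sha256"] = hashlib.sha256(cfg.encode()).hexdigest()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / f"{command.replace(' ', '_')}_log.json"
    log_path.write_text(json.dumps(payload, indent=1))
    return log_path
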