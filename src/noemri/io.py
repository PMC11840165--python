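"""NIfTI volume I/O, offset sidecars, and run configuration.

Volumes travel as NIfTI-1 with the voxel size in the affine; 4D spectral
stacks carry their saturation-offset list (ppm) in a JSON sidecar next to
the image — offsets are never inferred from volume order alone.  Masks must
share the stack's grid exactly: an orientation or shape mismatch is an
explicit error, never a silent resample.  Voxel indices are 0-based and
world coordinates go through the image affine.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .zspec import FrequencyAxis

__all__ = [
    "read_volume",
    "write_volume",
    "write_stack",
    "read_stack",
    "check_same_grid",
    "PipelineConfig",
]

logger = logging.getLogger("noemri")


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None,
                 voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write an array as NIfTI-1; returns the path written."""
    path = Path(path)
    if affine is None:
        affine = _affine(voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing volume: {path}")
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_stack(path, data4d: np.ndarray, axis: FrequencyAxis,
                affine: np.ndarray | None = None, voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a 4D spectral stack plus its offset sidecar (JSON, ppm)."""
    path = write_volume(path, data4d, affine=affine, voxel_size_mm=voxel_size_mm)
    sidecar = {
        "offsets_ppm": [float(x) for x in axis.offsets],
        "reference_offset_ppm": float(axis.reference_offset),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> tuple[np.ndarray, np.ndarray, FrequencyAxis]:
    """Read a 4D stack and its offset sidecar; returns (data, affine, axis)."""
    data, affine = read_volume(path)
    sidecar = _sidecar_path(Path(path))
    if not sidecar.exists():
        raise FileNotFoundError(f"missing offset sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    axis = FrequencyAxis(
        np.asarray(meta["offsets_ppm"], dtype=float),
        float(meta.get("reference_offset_ppm", 100.0)),
    )
    if data.shape[-1] != axis.n:
        raise ValueError(
            f"stack {Path(path).name} has {data.shape[-1]} volumes but sidecar lists {axis.n} offsets"
        )
    return data, affine, axis


def check_same_grid(name_a: str, shape_a, affine_a, name_b: str, shape_b, affine_b) -> None:
    """Refuse mismatched grids explicitly (no silent resampling)."""
    if tuple(shape_a[:3]) != tuple(shape_b[:3]):
        raise ValueError(
            f"grid mismatch: {name_a} has shape {tuple(shape_a[:3])} but "
            f"{name_b} has shape {tuple(shape_b[:3])}"
        )
    if affine_a is not None and affine_b is not None and not np.allclose(affine_a, affine_b):
        raise ValueError(f"orientation mismatch between {name_a} and {name_b} affines")


@dataclasses.dataclass
class PipelineConfig:
    """Serializable configuration for a full run.

    The effective config (including the seed) is written next to a run's
    outputs so any result can be regenerated from its log.
    """

    seed: int = 0
    output_dir: str = "noemri-out"
    verbosity: str = "INFO"
    phantom: dict = dataclasses.field(default_factory=dict)  # PhantomSpec overrides
    fit: dict = dataclasses.field(default_factory=dict)  # FitConfig overrides
    preprocess: dict = dataclasses.field(
        default_factory=lambda: {"denoise": "none", "denoise_sigma_vox": 1.0, "b1_floor": 0.3}
    )
    stats: dict = dataclasses.field(default_factory=lambda: {"equal_var": False})
    inputs: dict = dataclasses.field(default_factory=dict)  # paths for real data

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"missing config file: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
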