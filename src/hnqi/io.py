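"""NIfTI / CSV / JSON I/O and run configuration.

Volumes and masks travel as NIfTI-1 (.nii / .nii.gz) with the voxel size on
the affine diagonal; masks are uint8 {0, 1}. Tables are CSV, model reports
and configs JSON. DICOM is explicitly unsupported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid
from .subvolumes import Thresholds

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "RunConfig",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_volume(grid: VolumeGrid, path: str | Path, dtype=np.float32) -> Path:
    """Write a map as NIfTI-1; float32 by default."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=dtype), _affine(grid.voxel_size))
    img.header.set_zooms(grid.voxel_size)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, units: str = "") -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(data, zooms, units)


def write_mask(grid: VolumeGrid, path: str | Path) -> Path:
    vals = np.unique(grid.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask values must be {{0, 1}}, found {vals}")
    return write_volume(grid, path, dtype=np.uint8)


def read_mask(path: str | Path) -> VolumeGrid:
    grid = read_volume(path, units="mask")
    vals = np.unique(grid.data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask values must be {{0, 1}}, found {vals}")
    grid.data = grid.data.astype(np.uint8)
    return grid


def check_coregistered(*grids: VolumeGrid) -> None:
    """Hard error when modalities of one case disagree on grid geometry."""
    first = grids[0]
    for g in grids[1:]:
        if not first.same_grid(g):
            raise ValueError(
                "modalities are not co-registered: "
                f"{first.shape}@{first.voxel_size} vs {g.shape}@{g.voxel_size}"
            )


@dataclass
class RunConfig:
    """Configuration of a full synthetic run (phantom + cohort + models)."""

    output_dir: str = "results"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    # phantom geometry overrides (None -> library defaults)
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 3.0)
    n_patients: int = 54
    cox_betas: dict = field(default_factory=lambda: {"p16": -1.578, "adc_sd": 0.645})

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=list))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "thresholds" in raw:
            raw["thresholds"] = Thresholds(**raw["thresholds"])
        for key in ("grid_shape", "voxel_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_report(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    return path
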