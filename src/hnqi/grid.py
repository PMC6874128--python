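"""Volume containers shared by every stage of the pipeline.

All maps, masks and rendered modalities live on a common voxel grid; by
contract the phantom emits co-registered grids, so a shape + voxel-size
match is the only registration check the pipeline performs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid", "ParameterMaps"]


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values. Masks use uint8 {0, 1}; maps use floats. Invalid
        voxels in maps are NaN.
    voxel_size : tuple of float
        Spacing in mm along each axis; all entries positive.
    units : str
        Free-text unit tag, e.g. ``"mm^2/s"`` or ``"ml/100g"``.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if any(d < 1 for d in self.data.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def voxel_volume_cc(self) -> float:
        # 1 cc = 1000 mm^3
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size
        )

    def like(self, data: np.ndarray, units: str | None = None) -> "VolumeGrid":
        """New grid with the same geometry and different data."""
        return VolumeGrid(data, self.voxel_size, self.units if units is None else units)

    def mask_volume_cc(self) -> float:
        """Volume of the nonzero voxel set, in cm^3."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_cc


def _require_same_grid(*grids: VolumeGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.same_grid(g):
            raise ValueError(
                f"grid mismatch: {first.shape}@{first.voxel_size} vs {g.shape}@{g.voxel_size}"
            )


@dataclass
class ParameterMaps:
    """Per-voxel parametric maps for one case at one timepoint.

    adc in mm^2/s, ktrans and kep in 1/min, vp a unitless plasma fraction,
    bv in ml/100g, suv unitless. All maps share one grid.
    """

    adc: VolumeGrid
    ktrans: VolumeGrid
    kep: VolumeGrid
    vp: VolumeGrid
    bv: VolumeGrid
    suv: VolumeGrid

    def __post_init__(self) -> None:
        _require_same_grid(self.adc, self.ktrans, self.kep, self.vp, self.bv, self.suv)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.adc.voxel_size

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.adc.shape
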