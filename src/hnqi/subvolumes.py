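"""Threshold-defined tumor subvolumes and the adaptive-boost rule.

The clinician-drawn GTV is first cleaned of gross necrosis/cysts/vessels
(ADC above 2.7e-3 mm^2/s, i.e. 10% below free water) and air (ADC below
1e-7 mm^2/s); within the cleaned mask the low-blood-volume subvolume TV_BV
(BV < 7.64 ml/100g), the low-ADC subvolume TV_ADC (ADC < 1.2e-3 mm^2/s) and
the metabolic tumor volume MTV_50 (SUV > 50% of the top-4-voxel mean) are
cut. All threshold inequalities are strict, matching the printed "<"/">"
conventions. Subvolumes that persist from pre-RT to fraction 10 form the
boost target; a union below 1 cc routes the patient to observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import ParameterMaps, VolumeGrid

__all__ = [
    "Thresholds",
    "SubvolumeSet",
    "BoostDecision",
    "clean_gtv",
    "low_subvolume",
    "mtv50",
    "persisting",
    "boost_decision",
    "extract_subvolumes",
]


@dataclass(frozen=True)
class Thresholds:
    """Segmentation cutpoints. ADC thresholds in mm^2/s, BV in ml/100g."""

    adc_necrosis_hi: float = 2.7e-3  # exclude necrosis/cyst/vessel above this
    adc_air_lo: float = 0.0001e-3  # exclude air below this
    bv_low: float = 7.64  # TV_BV cut
    adc_low: float = 1.2e-3  # TV_ADC cut
    mtv_frac: float = 0.5  # MTV_50: fraction of the top-voxel reference
    mtv_top_voxels: int = 4  # voxels averaged for the SUV reference
    boost_min_cc: float = 1.0  # below this the patient goes to observation

    def __post_init__(self) -> None:
        if not self.adc_air_lo < self.adc_low < self.adc_necrosis_hi:
            raise ValueError("need adc_air_lo < adc_low < adc_necrosis_hi")
        if not 0 < self.mtv_frac < 1:
            raise ValueError("mtv_frac must be in (0, 1)")


def _check_grids(a: VolumeGrid, b: VolumeGrid) -> None:
    if not a.same_grid(b):
        raise ValueError("inputs must share one grid (co-registration contract)")


def _as_mask(grid: VolumeGrid, data: np.ndarray) -> VolumeGrid:
    return VolumeGrid(data.astype(np.uint8), grid.voxel_size, "mask")


def clean_gtv(gtv_mask: VolumeGrid, adc: VolumeGrid, thresholds: Thresholds) -> VolumeGrid:
    """Analysis mask: the GTV minus necrosis/vessel (ADC above the high cut),
    air (ADC below the low cut) and invalid (NaN) voxels."""
    _check_grids(gtv_mask, adc)
    inside = gtv_mask.data > 0
    a = adc.data
    keep = inside & np.isfinite(a) & (a <= thresholds.adc_necrosis_hi) & (a >= thresholds.adc_air_lo)
    if inside.any() and not keep.any():
        warnings.warn("analysis mask is empty after necrosis/air exclusion", stacklevel=2)
    if not inside.any():
        warnings.warn("empty GTV mask", stacklevel=2)
    return _as_mask(gtv_mask, keep)


def low_subvolume(
    map_grid: VolumeGrid,
    analysis_mask: VolumeGrid,
    cutoff: float,
    direction: str = "below",
) -> VolumeGrid:
    """Strict-threshold subvolume within the analysis mask.

    ``direction="below"`` keeps voxels with value < cutoff (TV_BV, TV_ADC);
    ``"above"`` keeps value > cutoff. A voxel exactly at the cutoff is
    excluded either way.
    """
    _check_grids(map_grid, analysis_mask)
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    inside = analysis_mask.data > 0
    v = map_grid.data
    with np.errstate(invalid="ignore"):
        sel = (v < cutoff) if direction == "below" else (v > cutoff)
    sel &= np.isfinite(v)
    return _as_mask(map_grid, inside & sel)


def mtv50(
    suv: VolumeGrid,
    gtv_mask: VolumeGrid,
    thresholds: Thresholds,
) -> tuple[VolumeGrid, float]:
    """Metabolic tumor volume at 50% of the top-voxel reference.

    The reference is the mean of the ``mtv_top_voxels`` largest SUV values
    inside the mask (values, not voxel identities, so ties at the 4th-largest
    value are deterministic); the mask keeps voxels with
    SUV > mtv_frac * reference. Returns (mask, reference).
    """
    _check_grids(suv, gtv_mask)
    inside = gtv_mask.data > 0
    values = suv.data[inside]
    values = values[np.isfinite(values)]
    if values.size == 0:
        warnings.warn("empty GTV: MTV undefined", stacklevel=2)
        return _as_mask(suv, np.zeros(suv.shape, dtype=bool)), float("nan")
    k = thresholds.mtv_top_voxels
    if values.size < k:
        warnings.warn(
            f"GTV has {values.size} voxels < {k}; using all for the SUV reference",
            stacklevel=2,
        )
        k = values.size
    top = np.sort(values)[-k:]
    reference = float(top.mean())
    cut = thresholds.mtv_frac * reference
    with np.errstate(invalid="ignore"):
        mask = inside & (suv.data > cut)
    return _as_mask(suv, mask), reference


def persisting(mask_pre: VolumeGrid, mask_mid: VolumeGrid, mode: str = "intersection") -> VolumeGrid:
    """Subvolume persisting from pre-RT to fraction 10.

    Default is the voxelwise intersection of the two timepoint masks on the
    common (co-registered) grid — the strictest reading of "persisting";
    ``mode="union"`` is available as the permissive alternative.
    """
    _check_grids(mask_pre, mask_mid)
    a = mask_pre.data > 0
    b = mask_mid.data > 0
    if mode == "intersection":
        out = a & b
    elif mode == "union":
        out = a | b
    else:
        raise ValueError("mode must be 'intersection' or 'union'")
    return _as_mask(mask_pre, out)


@dataclass(frozen=True)
class BoostDecision:
    target: VolumeGrid  # union of the persisting TV_BV and TV_ADC
    volume_cc: float
    eligible: bool  # False (< boost_min_cc) routes to the observation arm


def boost_decision(
    persist_bv: VolumeGrid,
    persist_adc: VolumeGrid,
    thresholds: Thresholds,
) -> BoostDecision:
    """Boost-target definition: union of the persisting low-BV and low-ADC
    subvolumes; eligible iff the union is at least ``boost_min_cc`` cm^3."""
    _check_grids(persist_bv, persist_adc)
    target = _as_mask(persist_bv, (persist_bv.data > 0) | (persist_adc.data > 0))
    vol = target.mask_volume_cc()
    return BoostDecision(target=target, volume_cc=vol, eligible=vol >= thresholds.boost_min_cc)


@dataclass
class SubvolumeSet:
    """All masks for one tumor at one timepoint, with volumes in cm^3."""

    gtv_mask: VolumeGrid
    analysis_mask: VolumeGrid
    tv_bv: VolumeGrid
    tv_adc: VolumeGrid
    mtv50: VolumeGrid
    mtv_reference_suv: float
    volumes_cc: dict[str, float]


def extract_subvolumes(
    maps: ParameterMaps,
    gtv_mask: VolumeGrid,
    thresholds: Thresholds | None = None,
) -> SubvolumeSet:
    """Run the full segmentation for one tumor at one timepoint.

    The MTV reference is computed over the cleaned analysis mask so that
    necrotic voxels never contribute, and every subvolume is nested in
    analysis_mask ⊆ gtv_mask.
    """
    thresholds = thresholds or Thresholds()
    analysis = clean_gtv(gtv_mask, maps.adc, thresholds)
    tv_bv = low_subvolume(maps.bv, analysis, thresholds.bv_low, "below")
    tv_adc = low_subvolume(maps.adc, analysis, thresholds.adc_low, "below")
    mtv_mask, ref = mtv50(maps.suv, analysis, thresholds)
    volumes = {
        "gtv_cc": gtv_mask.mask_volume_cc(),
        "analysis_cc": analysis.mask_volume_cc(),
        "tv_bv_cc": tv_bv.mask_volume_cc(),
        "tv_adc_cc": tv_adc.mask_volume_cc(),
        "mtv50_cc": mtv_mask.mask_volume_cc(),
    }
    return SubvolumeSet(
        gtv_mask=gtv_mask,
        analysis_mask=analysis,
        tv_bv=tv_bv,
        tv_adc=tv_adc,
        mtv50=mtv_mask,
        mtv_reference_suv=ref,
        volumes_cc=volumes,
    )
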