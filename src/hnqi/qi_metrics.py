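"""Per-tumor and per-patient quantitative-imaging metrics.

For each tumor and timepoint: subvolume sizes (GTV, TV_BV, TV_ADC, MTV_50),
mean ADC and mean BV over the cleaned GTV, mean/max SUV inside MTV_50, and
total lesion glycolysis TLG = MTV_50 volume x mean SUV in it. Change rates
at fraction 10 are (mid - pre) / pre, stored as fractions (a -16.2% volume
change is -0.162). Missing values stay missing (NaN) — they are never
silently zero — and patient-level aggregation sums volume-type metrics over
nodal tumors while averaging intensity-type metrics, skipping missing
entries with a contributor count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from math import isnan, nan

import numpy as np

from .grid import ParameterMaps
from .subvolumes import SubvolumeSet

__all__ = [
    "QIMetricRecord",
    "ChangeRecord",
    "tumor_metrics",
    "change_rate",
    "patient_aggregate",
    "VOLUME_METRICS",
    "INTENSITY_METRICS",
]

# volume-type metrics are summed over a patient's nodal tumors;
# intensity-type metrics are averaged (max_suv_mtv: mean of per-tumor maxima)
VOLUME_METRICS = ("gtv_cc", "tv_bv_cc", "tv_adc_cc", "mtv50_cc", "tlg")
INTENSITY_METRICS = ("mean_adc", "mean_bv", "mean_suv_mtv", "max_suv_mtv")


@dataclass
class QIMetricRecord:
    patient_id: str
    tumor_id: str
    kind: str  # primary | nodal
    timepoint: str  # pre | mid
    gtv_cc: float = nan
    tv_bv_cc: float = nan
    tv_adc_cc: float = nan
    mtv50_cc: float = nan
    mean_adc: float = nan  # mm^2/s over the analysis mask
    mean_bv: float = nan  # ml/100g over the analysis mask
    mean_suv_mtv: float = nan
    max_suv_mtv: float = nan
    tlg: float = nan  # cm^3 * SUV

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @property
    def mean_adc_um2_per_ms(self) -> float:
        """Mean ADC in the human-readable unit (1 μm^2/ms = 1e-3 mm^2/s)."""
        return self.mean_adc * 1000.0


@dataclass
class ChangeRecord:
    patient_id: str
    tumor_id: str
    metric: str
    rate: float  # dimensionless fraction, (mid - pre) / pre


def _masked_mean(data: np.ndarray, mask: np.ndarray) -> float:
    vals = data[mask > 0]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else nan


def tumor_metrics(
    maps: ParameterMaps,
    subvols: SubvolumeSet,
    patient_id: str,
    tumor_id: str,
    kind: str,
    timepoint: str,
) -> QIMetricRecord:
    """Extract the full metric vector for one tumor at one timepoint.

    An empty analysis mask leaves mean ADC/BV missing (with a warning); an
    empty MTV leaves the SUV statistics and TLG missing — volumes are still
    reported.
    """
    rec = QIMetricRecord(patient_id=patient_id, tumor_id=tumor_id, kind=kind, timepoint=timepoint)
    rec.gtv_cc = subvols.gtv_mask.mask_volume_cc()
    rec.tv_bv_cc = subvols.tv_bv.mask_volume_cc()
    rec.tv_adc_cc = subvols.tv_adc.mask_volume_cc()
    rec.mtv50_cc = subvols.mtv50.mask_volume_cc()

    if np.count_nonzero(subvols.analysis_mask.data) == 0:
        warnings.warn(
            f"tumor {tumor_id}/{timepoint}: empty analysis mask, intensity metrics missing",
            stacklevel=2,
        )
    else:
        rec.mean_adc = _masked_mean(maps.adc.data, subvols.analysis_mask.data)
        rec.mean_bv = _masked_mean(maps.bv.data, subvols.analysis_mask.data)

    if rec.mtv50_cc > 0:
        suv_in = maps.suv.data[subvols.mtv50.data > 0]
        suv_in = suv_in[np.isfinite(suv_in)]
        rec.mean_suv_mtv = float(suv_in.mean())
        rec.max_suv_mtv = float(suv_in.max())
        rec.tlg = rec.mtv50_cc * rec.mean_suv_mtv
    return rec


def change_rate(pre: QIMetricRecord, mid: QIMetricRecord, metric: str) -> ChangeRecord:
    """Fractional change of one metric at fraction 10: (mid - pre) / pre.

    Defined only when the pre value is present and positive; otherwise the
    rate is missing (NaN) with a warning.
    """
    if pre.tumor_id != mid.tumor_id:
        raise ValueError(f"tumor_id mismatch: {pre.tumor_id} vs {mid.tumor_id}")
    v_pre = getattr(pre, metric)
    v_mid = getattr(mid, metric)
    if v_pre is None or isnan(v_pre) or v_pre <= 0 or v_mid is None or isnan(v_mid):
        warnings.warn(
            f"change rate of {metric} undefined for {pre.tumor_id} (pre={v_pre})",
            stacklevel=2,
        )
        rate = nan
    else:
        rate = (v_mid - v_pre) / v_pre
    return ChangeRecord(pre.patient_id, pre.tumor_id, metric, rate)


def patient_aggregate(records: list[QIMetricRecord]) -> QIMetricRecord:
    """Aggregate a patient's nodal tumors into one record: volume-type
    metrics are summed, intensity-type metrics averaged over the tumors in
    which they are defined. TLG is a volume-type quantity and sums."""
    if not records:
        return QIMetricRecord(patient_id="", tumor_id="all_nodal", kind="nodal", timepoint="")
    pids = {r.patient_id for r in records}
    tps = {r.timepoint for r in records}
    if len(pids) > 1 or len(tps) > 1:
        raise ValueError("records must share patient_id and timepoint")
    agg = QIMetricRecord(
        patient_id=records[0].patient_id,
        tumor_id="all_nodal",
        kind="nodal",
        timepoint=records[0].timepoint,
    )
    for name in VOLUME_METRICS:
        vals = [getattr(r, name) for r in records if not isnan(getattr(r, name))]
        setattr(agg, name, float(np.sum(vals)) if vals else nan)
    for name in INTENSITY_METRICS:
        vals = [getattr(r, name) for r in records if not isnan(getattr(r, name))]
        setattr(agg, name, float(np.mean(vals)) if vals else nan)
    return agg
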