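"""First-order histogram features per lesion, per-patient aggregates, and
healthy white-matter ROI means.

Six histogram parameters are computed from each lesion's voxel values: mean,
median, and the 10th/25th/75th/90th percentiles.  Percentiles use linear
interpolation between order statistics at rank 1 + p*(n-1).  Per patient, the
six parameters are averaged across that patient's lesions with equal weight
per lesion (not voxel-weighted).  Healthy subjects contribute the mean APTw
of each of six white-matter ROIs; their subject-level value is the mean of
the six ROI means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

HISTOGRAM_PARAMS = ("mean", "median", "p10", "p25", "p75", "p90")


@dataclass
class LesionRecord:
    """Voxel APTw values (% water signal) of one segmented lesion."""

    patient_id: str
    group: str
    lesion_id: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("lesion values must be a flat list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("lesion values must be finite")

    @property
    def count(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class HistogramSummary:
    mean: float
    median: float
    p10: float
    p25: float
    p75: float
    p90: float

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in HISTOGRAM_PARAMS}


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    group: str
    n_lesions: int
    params: dict[str, float]


@dataclass(frozen=True)
class RoiMeasurement:
    subject_id: str
    region: str
    mean_aptw: float


def summarize_lesion(record: LesionRecord) -> HistogramSummary:
    """Six first-order histogram parameters of one lesion."""
    if record.count == 0:
        raise ValueError("cannot summarise an empty lesion record")
    v = record.values
    p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
    return HistogramSummary(mean=float(v.mean()), median=float(p50),
                            p10=float(p10), p25=float(p25),
                            p75=float(p75), p90=float(p90))


def aggregate_patient(records: list[LesionRecord]) -> PatientSummary:
    """Unweighted mean of each histogram parameter across one patient's lesions."""
    if not records:
        raise ValueError("patient has no lesions to aggregate")
    pid = records[0].patient_id
    group = records[0].group
    if any(r.patient_id != pid for r in records):
        raise ValueError("records belong to different patients")
    summaries = [summarize_lesion(r).as_dict() for r in records]
    params = {p: float(np.mean([s[p] for s in summaries])) for p in HISTOGRAM_PARAMS}
    return PatientSummary(patient_id=pid, group=group,
                          n_lesions=len(records), params=params)


def lesion_table(records: list[LesionRecord]) -> pd.DataFrame:
    """One row per lesion: identifiers, voxel count, six histogram parameters."""
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "group": r.group,
               "lesion_id": r.lesion_id, "n_voxels": r.count}
        row.update(summarize_lesion(r).as_dict())
        rows.append(row)
    cols = ["patient_id", "group", "lesion_id", "n_voxels", *HISTOGRAM_PARAMS]
    return pd.DataFrame(rows, columns=cols)


def patient_table(records: list[LesionRecord]) -> pd.DataFrame:
    """One row per patient: lesion count and per-parameter means across lesions."""
    rows = []
    by_patient: dict[str, list[LesionRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    for pid in sorted(by_patient):
        ps = aggregate_patient(by_patient[pid])
        row = {"patient_id": ps.patient_id, "group": ps.group,
               "n_lesions": ps.n_lesions}
        row.update(ps.params)
        rows.append(row)
    cols = ["patient_id", "group", "n_lesions", *HISTOGRAM_PARAMS]
    return pd.DataFrame(rows, columns=cols)


def roi_mean(mask: np.ndarray, aptw, subject_id: str = "", region: str = "") -> RoiMeasurement:
    """Arithmetic mean APTw over the valid voxels of one ROI."""
    values_vol = aptw.values if hasattr(aptw, "values") else np.asarray(aptw)
    if values_vol.shape != mask.shape:
        raise ValueError("ROI mask and APTw map do not share a grid")
    vals = values_vol[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no valid voxels")
    return RoiMeasurement(subject_id=subject_id, region=region,
                          mean_aptw=float(vals.mean()))


def roi_table(measurements: list[RoiMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": m.subject_id, "region": m.region, "mean_aptw": m.mean_aptw}
         for m in measurements],
        columns=["subject_id", "region", "mean_aptw"])


def subject_wm_values(rois: pd.DataFrame, level: str = "subject") -> pd.Series:
    """Healthy-WM values for group comparisons.

    level="subject" (default): one value per subject, the mean of its six ROI
    means.  level="roi": the individual ROI means.
    """
    if level == "subject":
        return rois.groupby("subject_id")["mean_aptw"].mean()
    if level == "roi":
        return rois["mean_aptw"]
    raise ValueError("level must be 'subject' or 'roi'")
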