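"""End-to-end pipeline: simulate -> map -> segment -> extract -> analyze.

A run is fully described by a RunConfig (serialisable to YAML); all
randomness flows from its seed, so identical configs give identical outputs.
Every exclusion decision (small lesions, segmentation leaks, uncorrectable
voxels) is counted in the run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial import ConvexHull

from . import features, io, mapping, phantom, segmentation, stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    seed: int = 0
    outdir: str = "aptw_run"
    cohort: dict = field(default_factory=dict)      # CohortSpec overrides
    max_b0: float = mapping.DEFAULT_MAX_B0_PPM
    seg_k: float = 2.0
    seg_grad_percentile: float = 90.0
    seg_max_voxels: int = 10_000
    min_lesion_voxels: int = segmentation.MIN_LESION_VOXELS
    fdr: float = stats.DEFAULT_FDR
    roi_area_mm2: float = 85.0
    save_volumes: bool = False

    def __post_init__(self) -> None:
        # normalise sequences to lists so YAML round trips compare equal
        for key, value in list(self.cohort.items()):
            if isinstance(value, tuple):
                self.cohort[key] = list(value)

    def cohort_spec(self) -> phantom.CohortSpec:
        overrides = dict(self.cohort)
        for key in ("lesions_per_patient", "grid_shape", "voxel_spacing"):
            if key in overrides:
                overrides[key] = tuple(overrides[key])
        if "lesion_axes" in overrides:
            overrides["lesion_axes"] = tuple(tuple(a) for a in overrides["lesion_axes"])
        overrides.setdefault("seed", self.seed)
        return phantom.CohortSpec(**overrides)

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def seed_outline_from_mask(lesion_mask: np.ndarray, spacing,
                           patient_id: str = "", lesion_id: int = 0) -> segmentation.SeedOutline:
    """Outline a ground-truth lesion the way a reader would: a polygon around
    the lesion's cross-section on its maximum-area slice.

    The polygon is the convex hull of the voxel centers of that slice,
    expanded by 0.2 voxel so boundary centers fall strictly inside; for convex
    cross-sections rasterisation recovers exactly those centers.
    """
    areas = lesion_mask.sum(axis=(0, 1))
    z = int(np.argmax(areas))
    if areas[z] == 0:
        raise ValueError("empty lesion mask")
    ix, iy = np.nonzero(lesion_mask[:, :, z])
    sx, sy = spacing[0], spacing[1]
    corners = []
    for dx in (-0.2, 0.2):
        for dy in (-0.2, 0.2):
            corners.append(np.column_stack([(ix + dx) * sx, (iy + dy) * sy]))
    pts = np.vstack(corners)
    hull = ConvexHull(pts)
    verts = tuple(map(tuple, pts[hull.vertices]))
    return segmentation.SeedOutline(slice_index=z, vertices_mm=verts,
                                    patient_id=patient_id, lesion_id=lesion_id)


def segment_subject(subject: phantom.Subject, aptw: mapping.APTwMap,
                    config: RunConfig) -> tuple[list[features.LesionRecord], dict]:
    """Seed, grow, size-filter and extract every ground-truth lesion of one subject."""
    records: list[features.LesionRecord] = []
    counts = {"seeded": 0, "leaks": 0, "filtered_small": 0, "segmented": 0}
    grad = ndimage.gaussian_gradient_magnitude(subject.flair.astype(float), sigma=1.0)
    masks: list[segmentation.LesionMask] = []
    for lesion_id in range(1, subject.n_lesions + 1):
        gt = subject.lesion_mask(lesion_id)
        outline = seed_outline_from_mask(gt, subject.spacing,
                                         patient_id=subject.subject_id,
                                         lesion_id=lesion_id)
        seed2d = segmentation.rasterize_seed(outline, subject.flair.shape, subject.spacing)
        counts["seeded"] += 1
        try:
            mask = segmentation.propagate_3d(
                subject.flair, seed2d, outline.slice_index,
                k=config.seg_k, grad_percentile=config.seg_grad_percentile,
                max_voxels=config.seg_max_voxels, grad=grad,
                patient_id=subject.subject_id, group=subject.group,
                lesion_id=lesion_id)
        except segmentation.SegmentationLeakError as exc:
            logger.warning("%s lesion %d: %s", subject.subject_id, lesion_id, exc)
            counts["leaks"] += 1
            continue
        masks.append(mask)
    kept = segmentation.filter_min_size(masks, min_voxels=config.min_lesion_voxels)
    counts["filtered_small"] = len(masks) - len(kept)
    for mask in kept:
        records.append(segmentation.extract_voxel_values(mask, aptw))
    counts["segmented"] = len(kept)
    return records, counts


def run_pipeline(config: RunConfig, outdir: Path | None = None) -> dict:
    """Execute the full pipeline on a synthetic cohort and write all tables.

    Returns the run report (also written as report.json).
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")

    spec = config.cohort_spec()
    cohort = phantom.generate_cohort(spec)
    logger.info("simulated %d subjects, %d lesions",
                len(cohort.subjects), len(cohort.lesion_table))
    if config.save_volumes:
        io.save_cohort(cohort, outdir / "cohort")

    all_records: list[features.LesionRecord] = []
    roi_measurements: list[features.RoiMeasurement] = []
    counts = {"seeded": 0, "leaks": 0, "filtered_small": 0, "segmented": 0,
              "uncorrectable_voxels": 0}
    for subject in cohort.subjects:
        zvol = mapping.ZSpectrumVolume.from_subject(subject)
        aptw = mapping.compute_aptw(zvol, subject.b0_map, max_b0=config.max_b0)
        counts["uncorrectable_voxels"] += aptw.n_uncorrectable
        if subject.group == phantom.GROUP_HEALTHY:
            rois = phantom.generate_healthy_rois(
                subject.flair.shape, subject.spacing, roi_area_mm2=config.roi_area_mm2)
            for region, m in rois.items():
                roi_measurements.append(
                    features.roi_mean(m, aptw, subject_id=subject.subject_id,
                                      region=region))
        else:
            records, sub_counts = segment_subject(subject, aptw, config)
            all_records.extend(records)
            for key in ("seeded", "leaks", "filtered_small", "segmented"):
                counts[key] += sub_counts[key]

    lesions = features.lesion_table(all_records)
    patients = features.patient_table(all_records)
    rois = features.roi_table(roi_measurements)
    lesions.to_csv(outdir / "lesions.csv", index=False)
    patients.to_csv(outdir / "patients.csv", index=False)
    rois.to_csv(outdir / "rois.csv", index=False)

    report: dict = {"counts": counts,
                    "n_subjects": len(cohort.subjects),
                    "n_lesions_ground_truth": int(len(cohort.lesion_table)),
                    "n_lesions_analyzed": int(len(lesions))}

    both_groups = (set(patients["group"]) >= {stats.POSITIVE_LABEL, stats.NEGATIVE_LABEL}
                   and all((patients["group"] == g).sum() >= 2
                           for g in (stats.POSITIVE_LABEL, stats.NEGATIVE_LABEL)))
    if both_groups:
        tests = stats.compare_groups(patients, fdr=config.fdr)
        roc = stats.roc_by_parameter(lesions)
        tests.to_csv(outdir / "group_tests.csv", index=False)
        roc.to_csv(outdir / "roc.csv", index=False)
        report["group_tests"] = tests.to_dict(orient="records")
        report["roc"] = roc.to_dict(orient="records")

    if len(rois) and both_groups:
        wm = features.subject_wm_values(rois).to_numpy()
        for g in (stats.POSITIVE_LABEL, stats.NEGATIVE_LABEL):
            vals = patients.loc[patients["group"] == g, "mean"].to_numpy()
            res = stats.wilcoxon_rank_sum(vals, wm)
            report[f"{g}_vs_healthy_p"] = res.pvalue

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


_PATIENT_ALIASES = ("patient_id", "patient", "subject_id", "subject", "id", "pat")
_GROUP_ALIASES = ("group", "label", "class", "type", "category", "diagnosis")
_LESION_ALIASES = ("lesion_id", "lesion", "roi", "roi_id", "lesion_number")
_VALUE_ALIASES = ("aptw_percent", "aptw", "apt", "value", "signal", "mtr_asym",
                  "mtrasym", "intensity", "aptw_signal")


def _match_column(columns, aliases) -> str | None:
    low = {c.lower().strip().replace(" ", "_"): c for c in columns}
    for alias in aliases:
        if alias in low:
            return low[alias]
    for alias in aliases:
        for norm, orig in low.items():
            if alias in norm:
                return orig
    return None


def read_supplementary_table(path: Path, sidecar: Path | None = None) -> pd.DataFrame:
    """Load a deposited per-voxel lesion table of unknown layout.

    Accepts delimited text (separator sniffed) or a spreadsheet; columns are
    matched by name against common aliases and normalised to the internal
    schema (patient_id, group, lesion_id, aptw_percent).  Extra columns are
    preserved in a sidecar CSV.  Rows with unparseable values are dropped and
    counted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise ValueError(f"{path} contains no data rows")

    mapping_cols = {}
    for target, aliases in (("patient_id", _PATIENT_ALIASES),
                            ("group", _GROUP_ALIASES),
                            ("lesion_id", _LESION_ALIASES),
                            ("aptw_percent", _VALUE_ALIASES)):
        col = _match_column(df.columns, aliases)
        if col is None:
            raise ValueError(
                f"cannot infer the '{target}' column; detected columns: {list(df.columns)}")
        mapping_cols[target] = col

    core = df[[mapping_cols[t] for t in ("patient_id", "group", "lesion_id",
                                         "aptw_percent")]].copy()
    core.columns = ["patient_id", "group", "lesion_id", "aptw_percent"]
    core["aptw_percent"] = pd.to_numeric(core["aptw_percent"], errors="coerce")
    n_bad = int(core["aptw_percent"].isna().sum())
    if n_bad:
        logger.warning("%d rows with unparseable APTw values dropped", n_bad)
        core = core.dropna(subset=["aptw_percent"])
    if core.empty:
        raise ValueError("no parseable rows in the supplementary table")

    extras = [c for c in df.columns if c not in mapping_cols.values()]
    if extras and sidecar is not None:
        df[extras].to_csv(sidecar, index=False)
    return core.reset_index(drop=True)


def records_from_table(table: pd.DataFrame) -> list[features.LesionRecord]:
    """Group a normalised voxel-value table into LesionRecords."""
    records = []
    for (pid, group, lid), sub in table.groupby(["patient_id", "group", "lesion_id"],
                                                sort=True):
        records.append(features.LesionRecord(
            patient_id=str(pid), group=str(group), lesion_id=int(lid),
            values=sub["aptw_percent"].to_numpy(dtype=float)))
    return records
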