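"""NIfTI and table I/O for the pipeline.

Volumes are written as NIfTI-1 with a diagonal affine from the voxel spacing.
One file per saturation offset plus the S0 reference, B0 map and FLAIR-like
volume; ground truth goes to CSV with a JSON sidecar holding the cohort spec.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mapping import APTwMap, B0Map, ZSpectrumVolume
from .phantom import Cohort, CohortSpec, Subject


def _affine(spacing) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def save_volume(data: np.ndarray, spacing, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))


def load_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), spacing


def _offset_tag(offset: float) -> str:
    sign = "m" if offset < 0 else "p"
    return f"{sign}{abs(offset):.1f}".replace(".", "_")


def save_subject(subject: Subject, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = subject.spacing
    for i, off in enumerate(subject.offsets):
        save_volume(subject.signals[i], sp, outdir / f"z_{_offset_tag(off)}.nii.gz")
    save_volume(subject.s0_volume, sp, outdir / "s0.nii.gz")
    save_volume(subject.b0_map, sp, outdir / "b0.nii.gz")
    save_volume(subject.flair, sp, outdir / "flair.nii.gz")
    save_volume(subject.mask.astype(np.uint8), sp, outdir / "mask.nii.gz")
    save_volume(subject.true_aptw, sp, outdir / "true_aptw.nii.gz")
    save_volume(subject.lesion_labels.astype(np.int16), sp, outdir / "lesion_labels.nii.gz")
    meta = {"subject_id": subject.subject_id, "group": subject.group,
            "offsets": list(subject.offsets)}
    (outdir / "subject.json").write_text(json.dumps(meta, indent=2))


def save_cohort(cohort: Cohort, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        save_subject(s, outdir / s.subject_id)
    cohort.lesion_table.to_csv(outdir / "ground_truth_lesions.csv", index=False)
    spec_dict = dataclasses.asdict(cohort.spec)
    (outdir / "cohort_spec.json").write_text(json.dumps(spec_dict, indent=2, default=list))


def load_zspectrum(zvol_paths: list[Path], offsets: list[float],
                   s0_path: Path, mask_path: Path | None = None) -> ZSpectrumVolume:
    if len(zvol_paths) != len(offsets):
        raise ValueError("one volume path per offset required")
    vols, spacing = [], None
    for p in zvol_paths:
        v, spacing = load_volume(p)
        vols.append(v)
    s0, _ = load_volume(s0_path)
    mask = None
    if mask_path is not None:
        mvol, _ = load_volume(mask_path)
        mask = mvol > 0
    return ZSpectrumVolume(offsets=tuple(offsets), signals=np.stack(vols),
                           s0=s0, mask=mask, spacing=spacing)


def load_b0(path: Path) -> B0Map:
    values, spacing = load_volume(path)
    return B0Map(values=values, spacing=spacing)


def save_aptw(aptw: APTwMap, path: Path) -> None:
    save_volume(aptw.values, aptw.spacing or (1.0, 1.0, 1.0), path)


def load_aptw(path: Path) -> APTwMap:
    values, spacing = load_volume(path)
    return APTwMap(values=values, spacing=spacing)


def spec_from_json(path: Path) -> CohortSpec:
    raw = json.loads(Path(path).read_text())
    for key in ("lesions_per_patient", "grid_shape", "voxel_spacing"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "lesion_axes" in raw:
        raw["lesion_axes"] = tuple(tuple(ax) for ax in raw["lesion_axes"])
    return CohortSpec(**raw)
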