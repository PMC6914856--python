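"""Synthetic CEST cohorts for end-to-end testing of the APTw pipeline.

Builds per-subject Z-spectrum volumes from a multi-pool Lorentzian model
(water + semisolid MT baseline centred at 0 ppm, an amide pool at +3.5 ppm
and a relayed-NOE pool at -3.5 ppm), together with a smooth B0 offset field,
a FLAIR-like anatomical volume with hyperintense lesions, and a ground-truth
table.  The cohort has the nested structure the analysis assumes: voxels
within lesions within patients, with group-level APTw means/SDs describing
the distribution of per-patient mean values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Saturation offsets acquired for asymmetry analysis (ppm from water).
PPM_OFFSETS: tuple[float, ...] = (-3.9, -3.5, -3.1, 3.1, 3.5, 3.9)
#: Far off-resonance acquisition used as the unsaturated reference (ppm).
REFERENCE_OFFSET_PPM: float = -1560.0
AMIDE_PPM: float = 3.5
NOE_PPM: float = -3.5

GROUP_MSL = "MSL"
GROUP_WMH = "WMH"
GROUP_HEALTHY = "HealthyWM"
LESION_GROUPS = (GROUP_MSL, GROUP_WMH)


@dataclass(frozen=True)
class PoolParams:
    """One saturation pool of the Z-spectrum model.

    amplitude : peak saturation as a fraction of S0, in [0, 1]
    width     : full width at half maximum, ppm (> 0)
    center    : resonance offset from water, ppm
    """

    amplitude: float
    width: float
    center: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError(f"pool amplitude must be in [0,1], got {self.amplitude}")
        if self.width <= 0:
            raise ValueError(f"pool width must be > 0, got {self.width}")

    def lorentzian(self, offsets_ppm):
        """Peak-normalised Lorentzian evaluated at the given offsets."""
        hw = 0.5 * self.width
        d = np.asarray(offsets_ppm, dtype=float) - self.center
        return self.amplitude * hw**2 / (d**2 + hw**2)


# Direct-water-saturation and semisolid MT baseline, both symmetric about
# 0 ppm so that all designed asymmetry at 3.5 ppm is carried by the
# amide-minus-NOE amplitude difference.  Amplitudes give Z(3.5 ppm) ~ 0.83,
# in the range seen at 2 uT saturation.
WATER_POOL = PoolParams(amplitude=0.80, width=1.4, center=0.0)
MT_POOL = PoolParams(amplitude=0.12, width=30.0, center=0.0)
AMIDE_WIDTH_PPM = 2.0
NOE_WIDTH_PPM = 4.0
#: Default NOE pool amplitude, in % of S0 (an assumption; see docs/methods.md).
DEFAULT_NOE_PERCENT = 2.0


def _cross_tail(width_ppm: float) -> float:
    """Lorentzian value at the mirror offset, 7 ppm from the peak, per unit amplitude."""
    hw = 0.5 * width_ppm
    return hw**2 / ((AMIDE_PPM - NOE_PPM) ** 2 + hw**2)


def _ref_terms(water: PoolParams, mt: PoolParams, amide_width: float, noe_width: float):
    """Baseline and unit pool tails at the far off-resonance reference offset."""
    baseline = float(water.lorentzian(REFERENCE_OFFSET_PPM)
                     + mt.lorentzian(REFERENCE_OFFSET_PPM))
    la_ref = float(PoolParams(1.0, amide_width, AMIDE_PPM).lorentzian(REFERENCE_OFFSET_PPM))
    ln_ref = float(PoolParams(1.0, noe_width, NOE_PPM).lorentzian(REFERENCE_OFFSET_PPM))
    return baseline, la_ref, ln_ref


def min_feasible_aptw_percent(noe_percent: float = DEFAULT_NOE_PERCENT,
                              amide_width: float = AMIDE_WIDTH_PPM,
                              noe_width: float = NOE_WIDTH_PPM,
                              water: PoolParams = WATER_POOL,
                              mt: PoolParams = MT_POOL) -> float:
    """Most negative APTw (%) realisable with a non-negative amide amplitude."""
    tn = _cross_tail(noe_width)
    an = noe_percent / 100.0
    baseline, _, ln_ref = _ref_terms(water, mt, amide_width, noe_width)
    return -100.0 * an * (1.0 - tn) / (1.0 - baseline - an * ln_ref)


def amide_amplitude(true_aptw_percent, noe_percent: float = DEFAULT_NOE_PERCENT,
                    amide_width: float = AMIDE_WIDTH_PPM,
                    noe_width: float = NOE_WIDTH_PPM,
                    water: PoolParams = WATER_POOL,
                    mt: PoolParams = MT_POOL):
    """Amide pool amplitude such that the noise-free, zero-shift MTR_asym at
    3.5 ppm -- normalised by the measured far off-resonance reference signal --
    equals ``true_aptw_percent`` exactly.

    With symmetric water/MT pools, (Z(-3.5) - Z(+3.5)) = Aa*(1 - t_a) -
    An*(1 - t_n), where t are the 7-ppm cross tails; the reference signal is
    1 minus all pool tails at -1560 ppm, so requiring the normalised asymmetry
    to equal r = true_aptw/100 gives a linear equation in Aa.
    """
    ta = _cross_tail(amide_width)
    tn = _cross_tail(noe_width)
    an = noe_percent / 100.0
    r = np.asarray(true_aptw_percent, dtype=float) / 100.0
    baseline, la_ref, ln_ref = _ref_terms(water, mt, amide_width, noe_width)
    aa = (r * (1.0 - baseline - an * ln_ref) + an * (1.0 - tn)) / (1.0 - ta + r * la_ref)
    if np.any(aa < 0):
        raise ValueError(
            "true_aptw below the feasible minimum "
            f"{min_feasible_aptw_percent(noe_percent, amide_width, noe_width):.3f}% "
            "for the given NOE amplitude"
        )
    return aa


def generate_zspectrum(true_aptw_percent,
                       b0_shift_ppm=0.0,
                       noe_percent: float = DEFAULT_NOE_PERCENT,
                       offsets: Sequence[float] = PPM_OFFSETS,
                       noise_sd: float = 0.0,
                       water: PoolParams = WATER_POOL,
                       mt: PoolParams = MT_POOL,
                       amide_width: float = AMIDE_WIDTH_PPM,
                       noe_width: float = NOE_WIDTH_PPM,
                       rng: np.random.Generator | None = None):
    """Simulate normalised Z-spectrum signals.

    A static-field offset of ``b0_shift_ppm`` makes the saturation applied at
    nominal offset ``o`` land at ``o - b0_shift`` relative to water, so the
    returned value at each nominal offset is the true spectrum evaluated at
    the shifted position.

    Parameters may be scalars or broadcastable arrays (e.g. whole volumes of
    per-voxel APTw targets and B0 shifts).

    Returns
    -------
    z : ndarray, shape (len(offsets),) + broadcast shape
        Signal fraction S(offset)/S0 at each nominal offset.
    z_ref : ndarray
        Signal fraction at the far off-resonance reference offset.
    """
    true_aptw = np.asarray(true_aptw_percent, dtype=float)
    b0 = np.asarray(b0_shift_ppm, dtype=float)
    true_aptw, b0 = np.broadcast_arrays(true_aptw, b0)

    aa = amide_amplitude(true_aptw, noe_percent, amide_width, noe_width,
                         water=water, mt=mt)
    an = noe_percent / 100.0
    amide = PoolParams(1.0, amide_width, AMIDE_PPM)   # unit amplitude, scaled below
    noe = PoolParams(1.0, noe_width, NOE_PPM)

    def spectrum_at(nominal):
        x = nominal - b0
        z = (1.0
             - water.lorentzian(x)
             - mt.lorentzian(x)
             - aa * amide.lorentzian(x)
             - an * noe.lorentzian(x))
        return z

    z = np.stack([spectrum_at(o) for o in offsets])
    z_ref = spectrum_at(REFERENCE_OFFSET_PPM)
    if np.any(z <= 0) or np.any(z_ref <= 0):
        raise ValueError("pool amplitudes sum above 1: negative signal is unphysical")
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        z = z + rng.normal(0.0, noise_sd, z.shape)
        z_ref = z_ref + rng.normal(0.0, noise_sd, z_ref.shape)
    return z, z_ref


def _default_group_dict(values: Mapping[str, float]) -> dict[str, float]:
    return dict(values)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    APTw quantities are in % water signal.  ``group_aptw_mean``/``sd``
    describe the across-patient distribution of per-patient mean lesion APTw
    (for the healthy group: of per-subject white-matter APTw).
    ``between_patient_sd`` defaults to the group SD so the across-patient
    spread reproduces the group SD; the patient/lesion/voxel variance split is
    otherwise a free parameter.
    """

    n_patients: Mapping[str, int] = field(
        default_factory=lambda: {GROUP_MSL: 27, GROUP_WMH: 35, GROUP_HEALTHY: 20})
    lesions_per_patient: tuple[int, int] = (5, 20)
    lesion_axes: tuple[tuple[float, float], ...] = ((1.8, 4.5), (1.8, 4.5), (1.0, 2.2))
    group_aptw_mean: Mapping[str, float] = field(
        default_factory=lambda: {GROUP_MSL: 0.72, GROUP_WMH: 0.52, GROUP_HEALTHY: 0.47})
    group_aptw_sd: Mapping[str, float] = field(
        default_factory=lambda: {GROUP_MSL: 0.24, GROUP_WMH: 0.35, GROUP_HEALTHY: 0.32})
    between_patient_sd: Mapping[str, float] | None = None
    between_lesion_sd: float = 0.10
    within_lesion_sd: float = 0.33
    background_aptw: float = 0.47
    b0_amplitude: float = 0.15
    signal_noise_sd: float = 0.002
    noe_percent: float = DEFAULT_NOE_PERCENT
    flair_background: float = 100.0
    flair_contrast: float = 50.0
    flair_noise_sd: float = 5.0
    grid_shape: tuple[int, int, int] = (64, 64, 14)
    voxel_spacing: tuple[float, float, float] = (0.9, 0.9, 3.85)
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("between_lesion_sd", "within_lesion_sd", "signal_noise_sd",
                     "flair_noise_sd", "b0_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for g, sd in self.group_aptw_sd.items():
            if sd < 0:
                raise ValueError(f"group_aptw_sd[{g}] must be >= 0")
        if self.lesions_per_patient[0] > self.lesions_per_patient[1]:
            raise ValueError("lesions_per_patient range inverted")
        if self.lesions_per_patient[0] < 0:
            raise ValueError("lesions_per_patient must be >= 0")
        lo_extent = [2 * hi + 3 for (_, hi) in self.lesion_axes]
        if any(g <= e for g, e in zip(self.grid_shape, lo_extent)) and \
                self.lesions_per_patient[1] > 0:
            raise ValueError("grid_shape too small for the requested lesion axes")

    def patient_sd(self, group: str) -> float:
        if self.between_patient_sd is not None:
            return float(self.between_patient_sd[group])
        return float(self.group_aptw_sd[group])


@dataclass
class Subject:
    """One synthetic subject: acquisition volumes plus ground truth."""

    subject_id: str
    group: str
    offsets: tuple[float, ...]
    signals: np.ndarray          # (n_offsets, nx, ny, nz), arbitrary units
    s0_volume: np.ndarray        # unsaturated reference volume
    b0_map: np.ndarray           # ppm
    flair: np.ndarray
    mask: np.ndarray             # brain mask (bool)
    true_aptw: np.ndarray        # % water signal, per voxel
    lesion_labels: np.ndarray    # int labels, 0 = background
    spacing: tuple[float, float, float]

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_labels.max())

    def lesion_mask(self, lesion_id: int) -> np.ndarray:
        return self.lesion_labels == lesion_id


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]
    lesion_table: pd.DataFrame   # patient_id, group, lesion_id, n_voxels, true_mean

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


def _smooth_b0_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Low-order polynomial field scaled to max |value| = amplitude (ppm)."""
    nx, ny, nz = shape
    u = np.linspace(-1, 1, nx)[:, None, None]
    v = np.linspace(-1, 1, ny)[None, :, None]
    w = np.linspace(-1, 1, nz)[None, None, :]
    c = rng.uniform(-1.0, 1.0, size=6)
    fld = (c[0] * u + c[1] * v + c[2] * w + c[3] * u * v
           + c[4] * (u**2 - 1.0 / 3.0) + c[5] * (v**2 - 1.0 / 3.0))
    peak = np.max(np.abs(fld))
    if peak > 0 and amplitude > 0:
        fld = fld * (amplitude / peak)
    else:
        fld = np.zeros(shape)
    return np.broadcast_to(fld, shape).copy()


def _ellipsoid_mask(shape, center, axes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[d] - center[d]) / axes[d]) ** 2 for d in range(3))
    return r2 <= 1.0


_DILATE = ndimage.generate_binary_structure(3, 3)


def _place_lesions(shape, n_lesions: int, axes_ranges, rng: np.random.Generator,
                   max_tries: int = 200) -> np.ndarray:
    """Disjoint ellipsoid labels (1..n) with a one-voxel gap between lesions."""
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    for lesion in range(1, n_lesions + 1):
        for attempt in range(max_tries):
            axes = [rng.uniform(lo, hi) for lo, hi in axes_ranges]
            center = [rng.uniform(a + 1.0, s - a - 2.0) for a, s in zip(axes, shape)]
            mask = _ellipsoid_mask(shape, center, axes)
            if mask.sum() < 10:
                continue  # below the minimum lesion size the study retains
            if not (mask & occupied).any():
                labels[mask] = lesion
                occupied |= ndimage.binary_dilation(mask, structure=_DILATE)
                break
        else:
            raise RuntimeError(
                f"could not place lesion {lesion}/{n_lesions} after {max_tries} tries; "
                "enlarge grid_shape or reduce lesion count/axes")
    return labels


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full synthetic cohort. Pure function of ``spec`` (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    feasible_min = min_feasible_aptw_percent(spec.noe_percent) + 1e-6
    subjects: list[Subject] = []
    rows: list[dict] = []

    for group in (GROUP_MSL, GROUP_WMH, GROUP_HEALTHY):
        n_sub = int(spec.n_patients.get(group, 0))
        for i in range(n_sub):
            sid = f"{group}_{i:03d}"
            patient_mean = rng.normal(spec.group_aptw_mean[group], spec.patient_sd(group))

            if group == GROUP_HEALTHY:
                background = patient_mean
                labels = np.zeros(spec.grid_shape, dtype=np.int32)
            else:
                background = spec.background_aptw
                lo, hi = spec.lesions_per_patient
                n_lesions = int(rng.integers(lo, hi + 1))
                labels = _place_lesions(spec.grid_shape, n_lesions, spec.lesion_axes, rng)

            true_aptw = rng.normal(background, spec.within_lesion_sd, spec.grid_shape)
            for lesion_id in range(1, int(labels.max()) + 1):
                m = labels == lesion_id
                lesion_target = rng.normal(patient_mean, spec.between_lesion_sd)
                true_aptw[m] = rng.normal(lesion_target, spec.within_lesion_sd, int(m.sum()))
                rows.append({"patient_id": sid, "group": group, "lesion_id": lesion_id,
                             "n_voxels": int(m.sum()),
                             "true_mean": float(true_aptw[m].mean())})
            n_clip = int(np.sum(true_aptw < feasible_min))
            if n_clip:
                logger.info("%s: clipped %d voxels at the feasible APTw floor", sid, n_clip)
                true_aptw = np.maximum(true_aptw, feasible_min)

            b0 = _smooth_b0_field(spec.grid_shape, spec.b0_amplitude, rng)
            z, z_ref = generate_zspectrum(
                true_aptw, b0_shift_ppm=b0, noe_percent=spec.noe_percent,
                offsets=PPM_OFFSETS, noise_sd=spec.signal_noise_sd, rng=rng)
            flair = (spec.flair_background
                     + spec.flair_contrast * (labels > 0)
                     + rng.normal(0.0, spec.flair_noise_sd, spec.grid_shape))

            subjects.append(Subject(
                subject_id=sid, group=group, offsets=PPM_OFFSETS,
                signals=z * spec.s0, s0_volume=z_ref * spec.s0,
                b0_map=b0, flair=flair,
                mask=np.ones(spec.grid_shape, dtype=bool),
                true_aptw=true_aptw, lesion_labels=labels,
                spacing=spec.voxel_spacing))

    columns = ["patient_id", "group", "lesion_id", "n_voxels", "true_mean"]
    table = pd.DataFrame(rows, columns=columns)
    return Cohort(spec=spec, subjects=subjects, lesion_table=table)


# Healthy white-matter ROI layout: three bilateral pairs on one slice.
_ROI_CENTERS = {          # (x fraction from midline, y fraction of extent)
    "frontal": 0.18,
    "centrum_semiovale": 0.50,
    "parietal": 0.82,
}


def generate_healthy_rois(grid_shape, voxel_spacing, roi_area_mm2: float = 85.0,
                          slice_index: int | None = None,
                          n_rois: int = 6) -> dict[str, np.ndarray]:
    """Six planar white-matter ROI masks: mirrored pairs in frontal, centrum
    semiovale and parietal positions, each with in-plane area ``roi_area_mm2``.

    Each ROI is the set of ``round(area / voxel_area)`` voxel centers nearest
    its center point; the right-hemisphere mask is the mirror image of the
    left one, so pairs have identical voxel counts.
    """
    if n_rois != 6:
        raise ValueError("the ROI protocol defines exactly 6 regions")
    if not 80.0 <= roi_area_mm2 <= 90.0:
        raise ValueError("roi_area_mm2 outside the protocol range [80, 90] mm^2")
    nx, ny, nz = grid_shape
    sx, sy, _ = voxel_spacing
    if slice_index is None:
        slice_index = nz // 2
    if not 0 <= slice_index < nz:
        raise ValueError("slice_index outside the volume")

    n_vox = int(round(roi_area_mm2 / (sx * sy)))
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    masks: dict[str, np.ndarray] = {}
    for region, yfrac in _ROI_CENTERS.items():
        cx_left = 0.28 * (nx - 1)
        cy = yfrac * (ny - 1)
        d2 = ((ix - cx_left) * sx) ** 2 + ((iy - cy) * sy) ** 2
        order = np.lexsort((iy.ravel(), ix.ravel(), d2.ravel()))
        sel = order[:n_vox]
        left2d = np.zeros((nx, ny), dtype=bool)
        left2d.ravel()[sel] = True
        right2d = left2d[::-1, :].copy()   # mirror across the x midline
        for side, m2d in (("L", left2d), ("R", right2d)):
            m = np.zeros(grid_shape, dtype=bool)
            m[:, :, slice_index] = m2d
            masks[f"{region}_{side}"] = m

    combined = np.zeros(grid_shape, dtype=int)
    for m in masks.values():
        combined += m
    if combined.max() > 1:
        raise ValueError("ROIs overlap: grid too small for the requested ROI area")
    return masks


def simulate_clustered_values(n_pos_patients: int = 27,
                              n_neg_patients: int = 35,
                              lesions_range: tuple[int, int] = (5, 20),
                              patient_sd: float = 0.15,
                              lesion_sd: float = 0.15,
                              delta: float = 0.0,
                              rng: np.random.Generator | None = None):
    """Lesion-level values with within-patient correlation, for studying the
    clustered AUC estimator.

    Values are Gaussian: patient effect (SD ``patient_sd``) plus lesion noise
    (SD ``lesion_sd``); positives are shifted by ``delta``.  The true AUC is
    Phi(delta / sqrt(2*(patient_sd^2 + lesion_sd^2))).

    Returns (values, labels, clusters) aligned arrays.
    """
    from scipy.stats import norm  # local: keep module import light

    if rng is None:
        rng = np.random.default_rng()
    values, labels, clusters = [], [], []
    cid = 0
    for label, n_pat, mu in ((GROUP_MSL, n_pos_patients, delta),
                             (GROUP_WMH, n_neg_patients, 0.0)):
        for _ in range(n_pat):
            n_les = int(rng.integers(lesions_range[0], lesions_range[1] + 1))
            patient_effect = rng.normal(mu, patient_sd)
            values.append(rng.normal(patient_effect, lesion_sd, n_les))
            labels += [label] * n_les
            clusters += [cid] * n_les
            cid += 1
    return np.concatenate(values), np.asarray(labels), np.asarray(clusters)


def true_auc_for_delta(delta: float, patient_sd: float = 0.15,
                       lesion_sd: float = 0.15) -> float:
    """Closed-form AUC of the Gaussian clustered model above."""
    from scipy.stats import norm

    return float(norm.cdf(delta / np.sqrt(2 * (patient_sd**2 + lesion_sd**2))))


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
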