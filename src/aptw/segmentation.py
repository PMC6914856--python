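"""Seed-based 3D lesion segmentation on a FLAIR-like volume.

The delineation protocol: the lesion is outlined once, as a closed planar
polygon on the slice where it shows its maximum diameter; the outline is
rasterised to a 2D seed mask; the full 3D extent is then recovered
automatically by region growing that combines an intensity threshold derived
from the seed statistics with an edge barrier derived from the local gradient
magnitude; finally lesions smaller than a minimum voxel count are dropped.

Committed parameterisation of the growing rule (both knobs exposed):
admit voxels with intensity >= mean(seed) - k*sd(seed) (k defaults to 2) and
gradient magnitude <= the q-th percentile (default 90) of the gradient over
the supra-threshold voxels inside a bounding box around the seed; the lesion
is the seed's 26-connected component of the admissible set.  Taking the
percentile over supra-threshold voxels (rather than the whole box) makes the
barrier cut the sharpest tenth of the candidate region -- its edges -- instead
of being dominated by the flat background surrounding a small lesion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path
from scipy import ndimage
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

MIN_LESION_VOXELS = 10


class SegmentationLeakError(RuntimeError):
    """Region growing escaped into background (runaway leak)."""


@dataclass(frozen=True)
class SeedOutline:
    """Manual 2D outline on the maximum-diameter slice.

    ``vertices_mm`` are (x, y) in-plane physical coordinates (mm), with the
    center of voxel (i, j) at (i*sx, j*sy).  The polygon must be simple and
    have at least 3 vertices.
    """

    slice_index: int
    vertices_mm: tuple[tuple[float, float], ...]
    patient_id: str = ""
    lesion_id: int = 0

    def __post_init__(self) -> None:
        if len(self.vertices_mm) < 3:
            raise ValueError("seed outline needs at least 3 vertices")


@dataclass
class LesionMask:
    """Single 26-connected lesion mask on the APTw reconstruction grid."""

    mask: np.ndarray
    patient_id: str = ""
    group: str = ""
    lesion_id: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def rasterize_seed(outline: SeedOutline, grid_shape, spacing) -> np.ndarray:
    """2D seed mask: voxels of the outline's slice whose centers fall inside
    the polygon (even-odd rule for simple polygons)."""
    nx, ny, nz = grid_shape
    sx, sy, _ = spacing
    if not 0 <= outline.slice_index < nz:
        raise ValueError("seed slice outside the volume")
    verts = np.asarray(outline.vertices_mm, dtype=float)
    extent_x, extent_y = (nx - 0.5) * sx, (ny - 0.5) * sy
    if (verts[:, 0].min() < -0.5 * sx or verts[:, 0].max() > extent_x
            or verts[:, 1].min() < -0.5 * sy or verts[:, 1].max() > extent_y):
        raise ValueError("seed polygon lies outside the grid bounds")
    xs = np.arange(nx) * sx
    ys = np.arange(ny) * sy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = Path(verts, closed=False).contains_points(pts)
    seed = inside.reshape(nx, ny)
    if not seed.any():
        raise ValueError("seed polygon contains no voxel centers")
    return seed


def propagate_3d(flair: np.ndarray,
                 seed2d: np.ndarray,
                 slice_index: int,
                 k: float = 2.0,
                 grad_percentile: float = 90.0,
                 max_voxels: int = 10_000,
                 margin: tuple[int, int, int] = (12, 12, 3),
                 grad_sigma: float = 1.0,
                 barrier_k: float = 2.0,
                 grad: np.ndarray | None = None,
                 patient_id: str = "",
                 group: str = "",
                 lesion_id: int = 0) -> LesionMask:
    """Grow the 2D seed into a 3D lesion mask.

    Parameters
    ----------
    k : admission threshold is mean(seed) - k * sd(seed); larger k admits more.
    grad_percentile : edge barrier is this percentile of the (Gaussian-smoothed)
        gradient magnitude over lesion-candidate voxels (intensity above the
        seed statistics at ``barrier_k``) within the seed's bounding box
        dilated by ``margin``.
    barrier_k : fixed multiplier defining the candidate set for the barrier
        percentile; kept independent of ``k`` so that relaxing the admission
        threshold can only grow the mask.
    max_voxels : leak guard; growth beyond this raises SegmentationLeakError.
    grad : optional precomputed gradient-magnitude volume (re-used across
        lesions of one subject).
    """
    if not seed2d.any():
        raise ValueError("empty seed")
    seed3d = np.zeros(flair.shape, dtype=bool)
    seed3d[:, :, slice_index] = seed2d

    seed_vals = flair[seed3d]
    threshold = float(seed_vals.mean() - k * seed_vals.std())

    if grad is None:
        grad = ndimage.gaussian_gradient_magnitude(flair.astype(float), sigma=grad_sigma)
    ix, iy = np.nonzero(seed2d)
    lo = [max(0, int(v)) for v in (ix.min() - margin[0], iy.min() - margin[1],
                                   slice_index - margin[2])]
    hi = [min(s, int(v) + 1) for s, v in zip(
        flair.shape, (ix.max() + margin[0], iy.max() + margin[1],
                      slice_index + margin[2]))]
    box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    barrier_threshold = float(seed_vals.mean() - barrier_k * seed_vals.std())
    candidates = grad[box][flair[box] >= barrier_threshold]
    barrier = float(np.percentile(candidates, grad_percentile)) if candidates.size \
        else float("inf")

    admissible = (flair >= threshold) & (grad <= barrier)
    admissible |= seed3d
    comps = cc_label(admissible, connectivity=3)
    seed_labels = comps[seed3d]
    lesion_label = np.bincount(seed_labels[seed_labels > 0]).argmax()
    mask = comps == lesion_label
    if mask.sum() > max_voxels:
        raise SegmentationLeakError(
            f"growth reached {int(mask.sum())} voxels (limit {max_voxels}); "
            f"threshold={threshold:.2f}, edge barrier={barrier:.3f}")
    return LesionMask(mask=mask, patient_id=patient_id, group=group, lesion_id=lesion_id)


def filter_min_size(masks: list[LesionMask],
                    min_voxels: int = MIN_LESION_VOXELS) -> list[LesionMask]:
    """Drop lesions with fewer than ``min_voxels`` voxels (logged)."""
    kept: list[LesionMask] = []
    for m in masks:
        if m.n_voxels >= min_voxels:
            kept.append(m)
        else:
            logger.info("lesion %s/%s excluded: %d voxels < %d",
                        m.patient_id, m.lesion_id, m.n_voxels, min_voxels)
    return kept


def extract_voxel_values(mask: LesionMask, aptw) -> "LesionRecord":
    """Per-voxel APTw values under the mask, excluding invalid (NaN) voxels."""
    from .features import LesionRecord  # local import to avoid a cycle

    values_vol = aptw.values if hasattr(aptw, "values") else np.asarray(aptw)
    if values_vol.shape != mask.mask.shape:
        raise ValueError("mask and APTw map do not share a grid")
    vals = values_vol[mask.mask]
    n_invalid = int(np.sum(~np.isfinite(vals)))
    if n_invalid:
        logger.info("lesion %s/%s: %d invalid voxels excluded",
                    mask.patient_id, mask.lesion_id, n_invalid)
    vals = vals[np.isfinite(vals)]
    return LesionRecord(patient_id=mask.patient_id, group=mask.group,
                        lesion_id=mask.lesion_id, values=vals)
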