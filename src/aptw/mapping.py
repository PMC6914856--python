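"""B0-corrected APTw mapping from Z-spectrum volumes.

The APTw metric is the magnetization transfer ratio asymmetry at 3.5 ppm,

    MTR_asym(%) = 100 * (S(-3.5 ppm) - S(+3.5 ppm)) / S0,

computed voxel-by-voxel after re-centring each voxel's Z-spectrum on its true
water resonance.  The acquired offsets (+-3.1, +-3.5, +-3.9 ppm) give three
samples per side of the spectrum; a static-field offset dB0 means that the
saturation nominally applied at offset o actually landed at o - dB0 from
water, so the measured samples on each side are treated as samples of the
spectrum at the shifted positions and the corrected value at +-3.5 ppm is
obtained by three-point (quadratic Lagrange) interpolation.  Evaluation
outside the shifted sample span is clamped to the nearest sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

TARGET_PPM = 3.5
#: Default bound on |dB0| beyond which a voxel is declared uncorrectable
#: (the sampled half-span of the acquired offsets).
DEFAULT_MAX_B0_PPM = 0.4


@dataclass
class B0Map:
    """Per-voxel static-field offset in ppm."""

    values: np.ndarray
    spacing: tuple[float, float, float] | None = None


@dataclass
class APTwMap:
    """Per-voxel MTR_asym at 3.5 ppm in % water signal; NaN where undefined."""

    values: np.ndarray
    spacing: tuple[float, float, float] | None = None
    n_uncorrectable: int = 0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class ZSpectrumVolume:
    """Saturation image stack plus unsaturated reference on one grid.

    ``signals[i]`` is the image acquired at ``offsets[i]`` (ppm); ``s0`` is the
    reference without saturation.  Offsets must come in symmetric +- pairs.
    Repeated offsets (e.g. several +3.5 ppm acquisitions) are averaged.
    """

    offsets: tuple[float, ...]
    signals: np.ndarray
    s0: np.ndarray
    mask: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.signals.shape[0] != len(self.offsets):
            raise ValueError("one signal volume per offset required")
        if self.signals.shape[1:] != self.s0.shape:
            raise ValueError("signal volumes and S0 must share one grid")
        if self.mask is None:
            self.mask = np.ones(self.s0.shape, dtype=bool)
        if self.mask.shape != self.s0.shape:
            raise ValueError("mask must share the volume grid")
        # collapse duplicate offsets by averaging
        uniq = sorted(set(self.offsets))
        if len(uniq) != len(self.offsets):
            offs = np.asarray(self.offsets)
            self.signals = np.stack(
                [self.signals[offs == o].mean(axis=0) for o in uniq])
            self.offsets = tuple(uniq)
        else:
            order = np.argsort(self.offsets)
            self.offsets = tuple(np.asarray(self.offsets)[order])
            self.signals = self.signals[order]
        pos = [o for o in self.offsets if o > 0]
        neg = [-o for o in self.offsets if o < 0]
        if sorted(pos) != sorted(neg):
            raise ValueError(f"offsets must form symmetric pairs, got {self.offsets}")

    @classmethod
    def from_subject(cls, subject) -> "ZSpectrumVolume":
        return cls(offsets=tuple(subject.offsets), signals=subject.signals,
                   s0=subject.s0_volume, mask=subject.mask, spacing=subject.spacing)


def normalize(zvol: ZSpectrumVolume) -> np.ndarray:
    """Z(offset) = S(offset)/S0 per voxel; NaN where S0 <= 0 or outside mask.

    Values are not clamped to [0, 1]: noise may push them slightly above 1 and
    clamping would bias the asymmetry.
    """
    invalid = (zvol.s0 <= 0) | ~zvol.mask
    n_bad_s0 = int(np.sum((zvol.s0 <= 0) & zvol.mask))
    if n_bad_s0:
        logger.warning("%d in-mask voxels with non-positive S0 flagged invalid", n_bad_s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = zvol.signals / zvol.s0
    z[:, invalid] = np.nan
    return z


def _lagrange3(x0, x1, x2, y0, y1, y2, t):
    """Quadratic Lagrange interpolation through three points, vectorised."""
    l0 = (t - x1) * (t - x2) / ((x0 - x1) * (x0 - x2))
    l1 = (t - x0) * (t - x2) / ((x1 - x0) * (x1 - x2))
    l2 = (t - x0) * (t - x1) / ((x2 - x0) * (x2 - x1))
    return y0 * l0 + y1 * l1 + y2 * l2


def _correct_side(offsets, z, b0, side: int, max_b0: float):
    """Corrected Z at side*3.5 ppm.  ``side`` is +1 or -1."""
    offs = np.asarray(offsets)
    side_offs = np.sort(offs[np.sign(offs) == side])
    if len(side_offs) < 3:
        raise ValueError("need at least 3 offsets per side for B0 correction")
    # the three samples closest to the target offset
    nearest = np.argsort(np.abs(side_offs - side * TARGET_PPM))[:3]
    side_offs = np.sort(side_offs[nearest])
    ys = [z[list(offsets).index(o)] for o in side_offs]
    b0 = np.asarray(b0, dtype=float)
    x0, x1, x2 = (o - b0 for o in side_offs)      # shifted sample positions
    t = np.clip(side * TARGET_PPM, x0, x2)        # clamp extrapolation
    corrected = _lagrange3(x0, x1, x2, ys[0], ys[1], ys[2], t)
    corrected = np.where(np.abs(b0) > max_b0, np.nan, corrected)
    return corrected


def b0_correct(offsets, z: np.ndarray, b0, max_b0: float = DEFAULT_MAX_B0_PPM):
    """Voxel-by-voxel B0 correction of normalised Z values.

    Returns ``(z_neg, z_pos)``: corrected Z at -3.5 and +3.5 ppm. Voxels with
    |dB0| > ``max_b0`` are flagged uncorrectable (NaN).
    """
    b0_values = b0.values if isinstance(b0, B0Map) else np.asarray(b0, dtype=float)
    offsets = tuple(offsets)
    z_neg = _correct_side(offsets, z, b0_values, -1, max_b0)
    z_pos = _correct_side(offsets, z, b0_values, +1, max_b0)
    return z_neg, z_pos


def mtr_asym(z_neg, z_pos) -> np.ndarray:
    """MTR_asym(%) = 100 * (Z(-3.5) - Z(+3.5)); negative values preserved."""
    return 100.0 * (np.asarray(z_neg, dtype=float) - np.asarray(z_pos, dtype=float))


def compute_aptw(zvol: ZSpectrumVolume, b0, max_b0: float = DEFAULT_MAX_B0_PPM) -> APTwMap:
    """Full mapping stage: normalise, B0-correct, take the 3.5 ppm asymmetry."""
    z = normalize(zvol)
    z_neg, z_pos = b0_correct(zvol.offsets, z, b0, max_b0=max_b0)
    values = mtr_asym(z_neg, z_pos)
    values[~zvol.mask] = np.nan
    n_unc = int(np.sum(~np.isfinite(values) & zvol.mask))
    if n_unc:
        logger.info("%d in-mask voxels uncorrectable or invalid", n_unc)
    return APTwMap(values=values, spacing=zvol.spacing, n_uncorrectable=n_unc)
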