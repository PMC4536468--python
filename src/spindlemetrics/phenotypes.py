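"""Per-cell phenotype classifiers.

Operational definitions: a division is asymmetric when the daughter size
ratio (max/min) strictly exceeds 1.2; a spindle is rotating when its
pole-identity-signed axis, projected to XY, turns by more than 90° net from
its initial orientation; a cell has partially unstable attachments when
strictly more than 30% of its sister pairs carry at least one
attachment-marker-negative kinetochore; minus-end intensity at the poles is
called asymmetric when the brighter pole exceeds the dimmer by a fold
threshold (analyst-set, default 1.5).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .geometry import PlateGeometry
from .kinetics import SisterPair, inter_kt_series
from .model import CellSeries

__all__ = [
    "DivisionCall",
    "RotationCall",
    "MinusEndCall",
    "detect_anaphase_onset",
    "detect_rotation",
    "classify_division",
    "classify_skap_cell",
    "classify_minus_end_asymmetry",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DivisionCall:
    size_a: float
    size_b: float
    ratio: float  # max/min >= 1
    asymmetric: bool  # ratio > 1.2 strictly (at the default threshold)


@dataclass(frozen=True)
class RotationCall:
    max_xy_angle_deg: float  # net orientation change, in [0, 180]
    cumulative_angle_deg: float  # summed |frame-to-frame| XY angle (exposed, not the call)
    rotating: bool  # max_xy_angle_deg > threshold


class MinusEndCall(str, enum.Enum):
    SYMMETRIC = "SYMMETRIC"
    POLE1_MORE = "POLE1_MORE"
    POLE2_MORE = "POLE2_MORE"


def detect_anaphase_onset(
    cell: CellSeries,
    pairs: list[SisterPair],
    fold: float = 1.5,
    baseline_frames: int = 3,
    sustain_frames: int = 2,
) -> int | None:
    """First frame of sustained sister separation, or None.

    The median inter-kinetochore distance across pairs must reach ``fold``
    times the median over the first ``baseline_frames`` frames and stay
    there for ``sustain_frames`` consecutive frames. A single-frame spike
    does not trigger.
    """
    if not pairs:
        return None
    frames = np.array(cell.frames)
    med = np.full(len(frames), np.nan)
    series = [inter_kt_series(p, frames) for p in pairs]
    stack = np.vstack(series)
    with np.errstate(all="ignore"):
        med = np.nanmedian(stack, axis=0)
    ok = np.isfinite(med)
    if ok.sum() < 5:
        return None
    base_vals = med[ok][:baseline_frames]
    baseline = float(np.median(base_vals))
    above = med >= fold * baseline
    run = 0
    for k in range(len(frames)):
        if not ok[k]:
            run = 0
            continue
        run = run + 1 if above[k] else 0
        if run >= sustain_frames:
            return int(frames[k - sustain_frames + 1])
    return None


def _xy_angle_between(v0: np.ndarray, v1: np.ndarray) -> float:
    """Unsigned angle (deg) between the XY projections of two signed axes."""
    a0, a1 = v0[:2], v1[:2]
    n0, n1 = np.linalg.norm(a0), np.linalg.norm(a1)
    if n0 < 1e-9 or n1 < 1e-9:
        raise ValueError("axis projection onto XY is degenerate")
    cosang = np.clip(a0 @ a1 / (n0 * n1), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def detect_rotation(
    geometry_by_frame: dict[int, PlateGeometry],
    threshold_deg: float = 90.0,
) -> RotationCall:
    """Net XY re-orientation of the pole-identity-signed spindle axis.

    The axis at each frame points from the non-reference toward the
    reference pole; the call compares each frame's XY projection with the
    first frame's and takes the maximum. Frames whose axis is parallel to Z
    are skipped with a warning.
    """
    frames = sorted(geometry_by_frame)
    if len(frames) < 2:
        raise ValueError("need geometry for at least 2 frames")
    axes = []
    for f in frames:
        geo = geometry_by_frame[f]
        v = geo.pole_ref_centroid - geo.pole_other_centroid
        if np.linalg.norm(v[:2]) < 1e-9:
            log.warning("frame %d: spindle axis parallel to Z; skipped", f)
            continue
        axes.append(v)
    if len(axes) < 2:
        raise ValueError("fewer than 2 frames with a usable XY axis projection")
    net = max(_xy_angle_between(axes[0], v) for v in axes[1:])
    cumulative = sum(_xy_angle_between(a, b) for a, b in zip(axes[:-1], axes[1:]))
    return RotationCall(
        max_xy_angle_deg=net,
        cumulative_angle_deg=cumulative,
        rotating=net > threshold_deg,
    )


def classify_division(size_a: float, size_b: float, threshold: float = 1.2) -> DivisionCall:
    """Daughter-size ratio call: asymmetric iff max/min strictly exceeds 1.2."""
    if size_a <= 0 or size_b <= 0:
        raise ValueError("daughter sizes must be > 0")
    ratio = max(size_a, size_b) / min(size_a, size_b)
    return DivisionCall(size_a=size_a, size_b=size_b, ratio=ratio,
                        asymmetric=ratio > threshold)


def classify_skap_cell(
    pair_intensities: list[tuple[float, float]],
    neg_rel_threshold: float = 0.3,
    frac_threshold: float = 0.3,
) -> tuple[bool, float, np.ndarray]:
    """Partially-unstable-attachment call from per-pair marker intensities.

    A kinetochore is marker-negative when its intensity falls below
    ``neg_rel_threshold`` times the cell median of all marker intensities;
    a pair counts as negative when at least one member is negative; the
    cell is positive when the negative-pair fraction strictly exceeds
    ``frac_threshold``. Returns (call, fraction, per-pair negative mask).
    """
    if not pair_intensities:
        raise ValueError("need at least one pair with marker intensities")
    arr = np.asarray(pair_intensities, dtype=float)
    cell_median = float(np.median(arr))
    cutoff = neg_rel_threshold * cell_median
    member_negative = arr < cutoff
    pair_negative = member_negative.any(axis=1)
    frac = float(pair_negative.mean())
    return frac > frac_threshold, frac, pair_negative


def classify_minus_end_asymmetry(i_pole1: float, i_pole2: float,
                                 fold: float = 1.5) -> MinusEndCall:
    """Fold-change call on pole minus-end intensities (threshold analyst-set)."""
    if i_pole1 < 0 or i_pole2 < 0:
        raise ValueError("intensities must be >= 0")
    if i_pole1 == 0 and i_pole2 == 0:
        raise ValueError("minus-end asymmetry undefined for two zero intensities")
    hi, lo = max(i_pole1, i_pole2), min(i_pole1, i_pole2)
    if lo == 0 or hi / lo > fold:
        return MinusEndCall.POLE1_MORE if i_pole1 > i_pole2 else MinusEndCall.POLE2_MORE
    return MinusEndCall.SYMMETRIC
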