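"""Per-frame 3D spindle geometry.

The half-spindle ratio R is the central quantity: fit a plane to the
kinetochore cloud (the metaphase plate), intersect it with the pole-to-pole
axis, and divide the half-spindle length L1 on the reference-pole side by
the opposite half-spindle length L2. The reference pole is the one carrying
the grandmother centriole (brightest centrin signal) — except in 2:1 cells,
where the 2-centriole pole is the numerator by convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .model import ConfigLabel

__all__ = [
    "GeometryError",
    "Pole",
    "PlateGeometry",
    "cluster_poles",
    "assign_reference_pole",
    "fit_plate_plane",
    "plate_metrics",
    "spindle_center_offset",
    "monopole_kt_distances",
    "pole_intensity_asymmetry",
]


class GeometryError(ValueError):
    pass


@dataclass
class Pole:
    """One spindle pole: centriole members and their centroid."""

    centroid: np.ndarray  # (3,) μm
    member_positions: np.ndarray  # (k, 3)
    member_intensities: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.member_positions = np.atleast_2d(np.asarray(self.member_positions, dtype=float))
        self.member_intensities = np.atleast_1d(np.asarray(self.member_intensities, dtype=float))
        d = np.linalg.norm(self.member_positions - self.centroid, axis=1)
        if np.any(d > 1.5):
            raise GeometryError("pole members more than 1.5 μm from centroid")

    @property
    def n_centrioles(self) -> int:
        return len(self.member_positions)

    @property
    def total_intensity(self) -> float:
        return float(self.member_intensities.sum())

    @property
    def max_intensity(self) -> float:
        return float(self.member_intensities.max())


@dataclass
class PlateGeometry:
    """Plane/axis intersection geometry of one frame.

    plane: n̂·x = d with |n̂| = 1; axis through the two pole centroids with
    unit direction û pointing from the non-reference toward the reference
    pole; L1 = |intersection − reference pole|, L2 likewise for the other
    pole; R = L1/L2. ``between_poles`` is False when the intersection falls
    outside the pole-to-pole segment (flagged, not fatal).
    """

    normal: np.ndarray
    offset: float
    axis_point: np.ndarray
    axis_dir: np.ndarray
    intersection: np.ndarray
    L1: float
    L2: float
    R: float
    reference_pole: int  # index into the (pole_ref, pole_other) pair: always 0
    between_poles: bool
    pole_ref_centroid: np.ndarray
    pole_other_centroid: np.ndarray

    @property
    def pole_distance(self) -> float:
        return float(np.linalg.norm(self.pole_ref_centroid - self.pole_other_centroid))


def cluster_poles(positions: np.ndarray, intensities: np.ndarray) -> tuple[Pole, Pole]:
    """Partition 2–4 centriole detections into two poles.

    Exhaustive search over all 2-group partitions (≤ 7 for n ≤ 4),
    minimizing the total within-group pairwise distance. Raises on fewer
    than 2 detections or when the best and runner-up partitions are
    indistinguishable (within 1e-6 μm).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    intensities = np.atleast_1d(np.asarray(intensities, dtype=float))
    n = len(positions)
    if n < 2:
        raise GeometryError(f"need at least 2 centriole detections, got {n}")
    if n > 4:
        raise GeometryError(f"at most 4 centriole detections supported, got {n}")
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)

    def within_cost(group: tuple[int, ...]) -> float:
        return sum(dist[i, j] for i, j in itertools.combinations(group, 2))

    best: tuple[float, tuple[int, ...]] | None = None
    second: float | None = None
    indices = list(range(n))
    # enumerate subsets containing index 0 to avoid mirror duplicates
    for r in range(1, n):
        for group_a in itertools.combinations(indices[1:], r - 1):
            a = (0,) + group_a
            b = tuple(i for i in indices if i not in a)
            if not b:
                continue
            cost = within_cost(a) + within_cost(b)
            if best is None or cost < best[0]:
                second = best[0] if best is not None else None
                best = (cost, a)
            elif second is None or cost < second:
                second = cost
    assert best is not None
    if second is not None and abs(second - best[0]) < 1e-6:
        raise GeometryError("ambiguous pole partition: two splits are equally good")
    a = list(best[1])
    b = [i for i in indices if i not in a]
    poles = tuple(
        Pole(
            centroid=positions[g].mean(axis=0),
            member_positions=positions[g],
            member_intensities=intensities[g],
        )
        for g in (a, b)
    )
    return poles  # type: ignore[return-value]


def assign_reference_pole(poles: tuple[Pole, Pole], config_label: ConfigLabel) -> int:
    """Index (0 or 1) of the reference (numerator) pole.

    2:1 cells: the 2-centriole pole, by convention. All other
    configurations: the pole containing the single brightest centriole
    detection (the grandmother).
    """
    a, b = poles
    if config_label == ConfigLabel.C21:
        if a.n_centrioles == b.n_centrioles:
            raise GeometryError("C21 cell but poles have equal centriole counts")
        return 0 if a.n_centrioles > b.n_centrioles else 1
    if abs(a.max_intensity - b.max_intensity) < 1e-9:
        raise GeometryError("brightest centriole intensity tie between poles")
    return 0 if a.max_intensity > b.max_intensity else 1


def fit_plate_plane(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Orthogonal least-squares plane through a kinetochore point cloud.

    The plane passes through the centroid; its normal is the smallest
    principal axis of the centered points (minimizes the sum of squared
    perpendicular distances). Returns (n̂, d) with n̂·x = d; the sign of n̂
    is arbitrary here and fixed by the caller against the spindle axis.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 3:
        raise GeometryError(f"plane fit needs >= 3 points, got {len(points)}")
    centroid = points.mean(axis=0)
    centered = points - centroid
    # principal axes of the centered cloud
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear cloud: the two smallest singular values both ~0
    scale = max(s[0], 1.0)
    if s[1] <= 1e-12 * scale:
        raise GeometryError("kinetochore points are collinear; plane undefined")
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    return normal, float(normal @ centroid)


def plate_metrics(
    plane: tuple[np.ndarray, float],
    poles: tuple[Pole, Pole],
    reference_pole: int,
) -> PlateGeometry:
    """Intersect the plate plane with the spindle axis and form R = L1/L2.

    The axis runs through the two pole centroids; û points toward the
    reference pole so that signed axis coordinates are positive on the
    reference side. The intersection solves n̂·(p0 + t·û) = d.
    """
    normal, d = plane
    normal = np.asarray(normal, dtype=float)
    ref = poles[reference_pole]
    other = poles[1 - reference_pole]
    p0 = other.centroid
    axis = ref.centroid - other.centroid
    dist = np.linalg.norm(axis)
    if dist <= 0:
        raise GeometryError("pole centroids coincide")
    u = axis / dist
    denom = normal @ u
    if abs(denom) <= 1e-6:
        raise GeometryError("spindle axis is parallel to the plate plane")
    if denom < 0:  # orient n̂ toward the reference pole
        normal, d, denom = -normal, -d, -denom
    t = (d - normal @ p0) / denom
    intersection = p0 + t * u
    L1 = float(np.linalg.norm(intersection - ref.centroid))
    L2 = float(np.linalg.norm(intersection - other.centroid))
    between = 0.0 <= t <= dist
    if not between:
        warnings.warn("plate/axis intersection falls outside the pole-to-pole segment",
                      stacklevel=2)
    if L2 == 0:
        raise GeometryError("intersection coincides with the non-reference pole")
    return PlateGeometry(
        normal=normal,
        offset=float(d),
        axis_point=p0,
        axis_dir=u,
        intersection=intersection,
        L1=L1,
        L2=L2,
        R=L1 / L2,
        reference_pole=0,
        between_poles=bool(between),
        pole_ref_centroid=ref.centroid.copy(),
        pole_other_centroid=other.centroid.copy(),
    )


def spindle_center_offset(poles: tuple[Pole, Pole], cortex_points: np.ndarray) -> float:
    """Distance between the spindle center and the cell center, μm.

    Spindle center: midpoint of the pole centroids (equidistant to both
    centrosomes). Cell center: midpoint of the two axis–cortex intersection
    points, taking on each side of the spindle center the cortex point
    closest to the axis and projecting it onto the axis.
    """
    cortex_points = np.atleast_2d(np.asarray(cortex_points, dtype=float))
    if len(cortex_points) < 2:
        raise GeometryError("need at least 2 cortex points")
    a, b = poles
    spindle_center = (a.centroid + b.centroid) / 2.0
    axis = a.centroid - b.centroid
    dist = np.linalg.norm(axis)
    if dist <= 0:
        raise GeometryError("pole centroids coincide")
    u = axis / dist
    rel = cortex_points - spindle_center
    s = rel @ u  # signed axis coordinate of each cortex point
    perp = np.linalg.norm(rel - np.outer(s, u), axis=1)
    sides = []
    for mask in (s > 0, s < 0):
        if not mask.any():
            raise GeometryError("cortex points all on one side of the spindle center")
        candidates = np.flatnonzero(mask)
        best = candidates[np.argmin(perp[candidates])]
        sides.append(spindle_center + s[best] * u)
    cell_center = (sides[0] + sides[1]) / 2.0
    return float(np.linalg.norm(spindle_center - cell_center))


def monopole_kt_distances(kt_points: np.ndarray, centriole_points: np.ndarray) -> np.ndarray:
    """Per-kinetochore Euclidean distance to the closest centriole, μm."""
    kt_points = np.atleast_2d(np.asarray(kt_points, dtype=float))
    centriole_points = np.atleast_2d(np.asarray(centriole_points, dtype=float))
    if len(kt_points) == 0 or len(centriole_points) == 0:
        raise GeometryError("need at least one kinetochore and one centriole")
    d = np.linalg.norm(kt_points[:, None, :] - centriole_points[None, :, :], axis=2)
    return d.min(axis=1)


def pole_intensity_asymmetry(i1: float, i2: float) -> float:
    """Normalized signed intensity difference (I1 − I2)/(I1 + I2) ∈ [−1, 1]."""
    if i1 < 0 or i2 < 0:
        raise ValueError("intensities must be >= 0")
    total = i1 + i2
    if total == 0:
        raise ValueError("pole intensity asymmetry undefined for two zero intensities")
    return (i1 - i2) / total
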