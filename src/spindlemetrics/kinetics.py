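"""Sister-kinetochore pairing, distances and oscillation analysis.

Inter-kinetochore distance (inner marker to inner marker across a sister
pair) proxies centromere tension; the intra-kinetochore distance δ is half
the difference between the outer–outer and inner–inner sister distances.
Sister oscillations along the spindle axis are summarized by the
normalized autocorrelation of the axis-projected pair-center position; the
lag of the first local minimum estimates the half-period and its depth the
regularity of the oscillation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import Track

__all__ = [
    "SisterPair",
    "SisterPairSet",
    "ACProfile",
    "pair_sisters",
    "pair_tracks",
    "inter_kt_series",
    "intra_kt_delta",
    "axis_position_series",
    "oscillation_autocorrelation",
    "average_profiles",
    "half_period",
]

log = logging.getLogger(__name__)


@dataclass
class SisterPair:
    track_a: Track
    track_b: Track

    def common_frames(self) -> np.ndarray:
        return np.intersect1d(self.track_a.frames, self.track_b.frames)


@dataclass
class SisterPairSet:
    pairs: list[SisterPair]
    n_unpaired: int


@dataclass
class ACProfile:
    """Normalized autocorrelation on the lag grid 0, dt, 2dt, ..."""

    lags_s: np.ndarray
    ac: np.ndarray
    n_series: int = 1

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lags must ascend")
        if np.nanmax(np.abs(self.ac)) > 1 + 1e-9:
            raise ValueError("|ac| must not exceed 1")


def pair_sisters(points: np.ndarray, max_pair_um: float = 2.0) -> tuple[list[tuple[int, int]], list[int]]:
    """Pair kinetochore points of one frame by mutual proximity.

    Candidate pairs within the gate are accepted greedily in increasing
    distance order (ties broken by lowest indices), each point used at most
    once — the iterated closest-pair rule, which accepts exactly the
    mutual-nearest-neighbor pairs at each stage. Returns (pairs, unpaired
    indices).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n < 2:
        return [], list(range(n))
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    candidates = sorted(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n) if d[i, j] <= max_pair_um),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if used[i] or used[j]:
            continue
        pairs.append((i, j))
        used[i] = used[j] = True
    unpaired = [int(i) for i in np.flatnonzero(~used)]
    if not pairs:
        log.warning("no sister pairs found within %.2f μm gate", max_pair_um)
    return pairs, unpaired


def pair_tracks(tracks: list[Track], max_pair_um: float = 2.0) -> SisterPairSet:
    """Pair kinetochore tracks using their earliest common frame.

    Tracks are paired at the first frame where at least two tracks are
    sampled, applying :func:`pair_sisters` to the positions at that frame.
    """
    if len(tracks) < 2:
        return SisterPairSet(pairs=[], n_unpaired=len(tracks))
    frame0 = min(int(t.frames[0]) for t in tracks)
    present = [t for t in tracks if t.position_at(frame0) is not None]
    rest = [t for t in tracks if t.position_at(frame0) is None]
    pts = np.array([t.position_at(frame0) for t in present])
    idx_pairs, unpaired = pair_sisters(pts, max_pair_um)
    pairs = [SisterPair(present[i], present[j]) for i, j in idx_pairs]
    return SisterPairSet(pairs=pairs, n_unpaired=len(unpaired) + len(rest))


def inter_kt_series(pair: SisterPair, frames: np.ndarray | None = None) -> np.ndarray:
    """Per-frame sister-to-sister Euclidean distance, NaN where either is missing."""
    if frames is None:
        lo = min(pair.track_a.frames[0], pair.track_b.frames[0])
        hi = max(pair.track_a.frames[-1], pair.track_b.frames[-1])
        frames = np.arange(lo, hi + 1)
    out = np.full(len(frames), np.nan)
    for k, f in enumerate(frames):
        pa = pair.track_a.position_at(int(f))
        pb = pair.track_b.position_at(int(f))
        if pa is not None and pb is not None:
            out[k] = np.linalg.norm(pa - pb)
    return out


def intra_kt_delta(d_inner_um: float, d_outer_um: float) -> float:
    """δ = (outer–outer − inner–inner)/2; may be negative under noise."""
    if d_inner_um < 0 or d_outer_um < 0:
        raise ValueError("distances must be >= 0")
    return (d_outer_um - d_inner_um) / 2.0


def axis_position_series(pair: SisterPair, geometry_by_frame: dict[int, "object"],
                         frames: np.ndarray | None = None) -> np.ndarray:
    """Signed projection of the pair center onto the spindle axis, per frame.

    Origin at the spindle center (midpoint of the pole centroids); positive
    toward the reference pole. NaN where either sister or the frame
    geometry is missing.
    """
    if frames is None:
        lo = min(pair.track_a.frames[0], pair.track_b.frames[0])
        hi = max(pair.track_a.frames[-1], pair.track_b.frames[-1])
        frames = np.arange(lo, hi + 1)
    out = np.full(len(frames), np.nan)
    for k, f in enumerate(frames):
        geo = geometry_by_frame.get(int(f))
        pa = pair.track_a.position_at(int(f))
        pb = pair.track_b.position_at(int(f))
        if geo is None or pa is None or pb is None:
            continue
        center = (pa + pb) / 2.0
        spindle_center = (geo.pole_ref_centroid + geo.pole_other_centroid) / 2.0
        out[k] = geo.axis_dir @ (center - spindle_center)
    return out


def oscillation_autocorrelation(series: np.ndarray, dt_s: float,
                                max_lag_s: float | None = None) -> ACProfile:
    """Mean-subtracted, biased-normalized autocorrelation of one series.

    ac[k] = Σₜ x̃ₜ x̃ₜ₊ₖ / Σₜ x̃ₜ² on the lag grid 0, dt, 2dt, ... Gaps
    (NaN) are tolerated up to 20% of the frames: products over valid pairs
    are averaged and rescaled by the biased taper (N−k)/N, which reduces to
    the standard biased estimator for gap-free series. Requires ≥ 8 valid
    samples; a constant series has no defined oscillation and raises.
    """
    x = np.asarray(series, dtype=float)
    valid = np.isfinite(x)
    n = len(x)
    if valid.sum() < 8:
        raise ValueError(f"need >= 8 valid samples, got {int(valid.sum())}")
    if n and (n - valid.sum()) / n > 0.20:
        raise ValueError("more than 20% of frames are gaps")
    xm = x - np.nanmean(x)
    var = np.nanmean(xm**2)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("constant series: zero variance")
    max_lag = n - 1 if max_lag_s is None else min(n - 1, int(np.floor(max_lag_s / dt_s)))
    ac = np.full(max_lag + 1, np.nan)
    for k in range(max_lag + 1):
        prod = xm[: n - k] * xm[k:] if k else xm * xm
        ok = np.isfinite(prod)
        if not ok.any():
            continue
        ac[k] = prod[ok].mean() * ((n - k) / n) / var
    ac[0] = 1.0
    lags = np.arange(max_lag + 1) * dt_s
    return ACProfile(lags_s=lags, ac=np.clip(ac, -1.0, 1.0), n_series=1)


def average_profiles(profiles: list[ACProfile]) -> ACProfile:
    """Pointwise average of autocorrelation profiles (equal weight each)."""
    if not profiles:
        raise ValueError("no profiles to average")
    n = min(len(p.ac) for p in profiles)
    lags = profiles[0].lags_s[:n]
    for p in profiles:
        if not np.allclose(p.lags_s[:n], lags):
            raise ValueError("profiles are on different lag grids")
    stack = np.vstack([p.ac[:n] for p in profiles])
    return ACProfile(lags_s=lags, ac=np.nanmean(stack, axis=0), n_series=len(profiles))


def half_period(profile: ACProfile, min_depth: float = -0.1) -> tuple[float | None, float | None]:
    """Lag and depth of the first strict local minimum of the autocorrelation.

    Only minima deeper than ``min_depth`` qualify (rejects shallow noise
    dips). Returns (None, None) when no qualifying minimum exists — e.g.
    for white noise.
    """
    ac = profile.ac
    lags = profile.lags_s
    for k in range(1, len(ac) - 1):
        if np.isnan(ac[k - 1]) or np.isnan(ac[k]) or np.isnan(ac[k + 1]):
            continue
        if ac[k] < ac[k - 1] and ac[k] < ac[k + 1] and ac[k] < min_depth:
            return float(lags[k]), float(ac[k])
    return None, None
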