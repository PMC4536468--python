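"""Synthetic metaphase-spindle generator with known ground truth.

Emulates fluorescence time-lapse imaging of HeLa metaphase cells carrying a
centriole marker (centrin) and an inner-kinetochore marker (CENPA): two
spindle poles ~10 μm apart, ~20–46 sister-kinetochore pairs congressed on a
metaphase plate, a plate/axis intersection dividing the pole-to-pole
segment at a target half-spindle ratio R, quasi-periodic sister
oscillations along the axis, isotropic localization noise, optional
in-plane spindle rotation, exponential relaxation of the plate offset
toward the spindle center, and an optional anaphase onset after which
sister separation ramps up. Every emitted cell comes with a
:class:`TrueCellParams` record so downstream estimators can be scored
against ground truth.

The default imaging regime follows the live-cell assay being emulated:
5-minute videos sampled every 7.5 s (the long-video regime is 15 min at
30-s intervals). Centriole brightness encodes age: the grandmother is
strictly brightest (levels 4:3:2:2 for grandmother:mother:daughters).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import CellSeries, Channel, ConfigLabel, DETECTION_COLUMNS

__all__ = ["SimConfig", "TrueCellParams", "simulate_cell", "simulate_cohort",
           "simulate_fixed_snapshot", "truth_to_frame"]

# centrin brightness levels, grandmother:mother:daughter:daughter
_CENTRIN_LEVELS = {"grandmother": 400.0, "mother": 300.0, "daughter": 200.0}
_KT_INTENSITY = 1000.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    ``r_true`` is the target half-spindle ratio; with ``r_sigma`` > 0 the
    per-cell initial ratio is lognormal around it (median = ``r_true``).
    The default spread 0.13 reproduces the dispersion of live metaphase
    populations (~24% of a centered cohort outside the 0.85/1.15
    boundaries; ~40% of a median-1.12 cohort above 1.15).
    """

    n_cells: int = 1
    config_label: ConfigLabel = ConfigLabel.C22
    pole_distance_um: float = 10.0
    n_pairs: int = 23
    r_true: float = 1.0
    r_sigma: float = 0.13
    inter_kt_um: float = 1.0
    plate_radius_um: float = 4.5
    pair_min_spacing_um: float = 1.5
    osc_amplitude_um: float = 0.3
    osc_period_s: float = 80.0
    noise_sigma_um: float = 0.05
    rotation_deg_per_min: float = 0.0
    centering_tau_s: float | None = None
    anaphase_at_s: float | None = None
    duration_s: float = 300.0
    dt_s: float = 7.5
    cell_half_length_um: float = 9.0
    spindle_center_offset_um: float = 0.5
    # fixed-snapshot parameters
    delta_um: float = 0.110
    skap_negative_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.config_label, ConfigLabel):
            object.__setattr__(self, "config_label", ConfigLabel(self.config_label))
        for name in ("pole_distance_um", "inter_kt_um", "plate_radius_um",
                     "duration_s", "dt_s", "cell_half_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_pairs < 1 or self.n_cells < 1:
            raise ValueError("n_pairs and n_cells must be >= 1")
        if self.r_true <= 0 or self.r_sigma < 0:
            raise ValueError("r_true must be > 0 and r_sigma >= 0")
        if self.noise_sigma_um < 0 or self.osc_amplitude_um < 0 or self.osc_period_s <= 0:
            raise ValueError("invalid oscillation/noise parameters")
        n_steps = self.duration_s / self.dt_s
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt_s must divide duration_s")
        if self.delta_um < 0:
            raise ValueError("delta_um must be >= 0")
        if not 0.0 <= self.skap_negative_fraction <= 1.0:
            raise ValueError("skap_negative_fraction must be in [0, 1]")
        if self.cell_half_length_um <= self.pole_distance_um / 2:
            raise ValueError("cell must be longer than the spindle")


@dataclass
class TrueCellParams:
    """Ground truth paired with one simulated cell."""

    cell_id: str
    times_s: np.ndarray  # (T,)
    r_true: np.ndarray  # (T,) half-spindle ratio over time
    pole_ref: np.ndarray  # (T, 3) reference-pole centroid (centriole mean)
    pole_other: np.ndarray  # (T, 3)
    plate_point: np.ndarray  # (T, 3) plane/axis intersection
    rotation_deg: np.ndarray  # (T,) net XY rotation from the initial axis
    inter_kt_um: np.ndarray  # (T,) sister separation (rest length + ramp)
    sister_ref: np.ndarray  # (T, P, 3) noiseless reference-side sister positions
    sister_other: np.ndarray  # (T, P, 3)
    delta_true_um: float
    anaphase_frame: int | None
    daughter_size_ref: float  # axis segment length on the reference side, μm
    daughter_size_other: float
    skap_negative_pairs: np.ndarray  # (P,) bool
    skap_negative_member: np.ndarray  # (P,) 0 = reference-side sister, 1 = other

    @property
    def daughter_ratio(self) -> float:
        a, b = self.daughter_size_ref, self.daughter_size_other
        return max(a, b) / min(a, b)


def _centriole_layout(label: ConfigLabel) -> tuple[list[float], list[float]]:
    """(reference-pole levels, other-pole levels) of centrin intensity."""
    g, m, d = (_CENTRIN_LEVELS[k] for k in ("grandmother", "mother", "daughter"))
    if label in (ConfigLabel.WT, ConfigLabel.C22):
        return [g, d], [m, d]
    if label == ConfigLabel.C21:
        # the 2-centriole pole is the reference pole by convention
        return [g, d], [m]
    if label == ConfigLabel.C11:
        return [g], [m]
    raise ValueError(f"unknown config label {label}")


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _poisson_disc(rng: np.random.Generator, n: int, radius: float,
                  min_dist: float, max_tries: int = 5000,
                  max_restarts: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Dart-throwing placement of n points in a disc with a minimum spacing.

    Restarts from scratch when a configuration jams before reaching n.
    """
    for _ in range(max_restarts):
        pts: list[np.ndarray] = []
        for _ in range(max_tries):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            rad = radius * np.sqrt(rng.uniform())
            p = np.array([rad * np.cos(phi), rad * np.sin(phi)])
            if all(np.linalg.norm(p - q) >= min_dist for q in pts):
                pts.append(p)
                if len(pts) == n:
                    arr = np.array(pts)
                    return arr[:, 0], arr[:, 1]
    raise ValueError(
        f"could not place {n} pairs with spacing {min_dist} μm in a "
        f"{radius} μm plate; lower n_pairs or the spacing"
    )


def simulate_cell(cfg: SimConfig, index: int = 0) -> tuple[CellSeries, TrueCellParams]:
    """Simulate one cell; deterministic given (cfg.seed, index)."""
    rng = _cell_rng(cfg.seed, index)
    cell_id = f"sim{cfg.seed}_{index:04d}"
    n_frames = int(round(cfg.duration_s / cfg.dt_s)) + 1
    times = np.arange(n_frames) * cfg.dt_s

    # initial ratio (lognormal around target; median = r_true)
    r0 = cfg.r_true if cfg.r_sigma == 0 else cfg.r_true * float(np.exp(rng.normal(0.0, cfg.r_sigma)))

    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    omega = np.deg2rad(cfg.rotation_deg_per_min) / 60.0  # rad/s

    ref_levels, other_levels = _centriole_layout(cfg.config_label)
    # static centriole offsets in the spindle frame (axis, e1, e2), ≤0.25 μm
    def _ball(n: int) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return v * (0.25 * rng.uniform(0.0, 1.0, size=(n, 1)) ** (1 / 3))

    off_ref = _ball(len(ref_levels))
    off_other = _ball(len(other_levels))
    # pole centroid = mean of member positions; subtract the mean so the
    # nominal pole position is the centroid exactly
    off_ref -= off_ref.mean(axis=0)
    off_other -= off_other.mean(axis=0)

    # pair plate coordinates: Poisson-disk placement in the plate disc, so
    # that pair centers are farther apart than the sister rest length and
    # mutual-nearest-neighbor pairing is well posed
    q1, q2 = _poisson_disc(rng, cfg.n_pairs, cfg.plate_radius_um, cfg.pair_min_spacing_um)
    osc_phase = rng.uniform(0.0, 2.0 * np.pi, cfg.n_pairs)

    # SKAP ground truth (used by fixed snapshots; carried for uniformity)
    n_neg = int(round(cfg.skap_negative_fraction * cfg.n_pairs))
    neg_idx = rng.choice(cfg.n_pairs, size=n_neg, replace=False)
    skap_negative = np.zeros(cfg.n_pairs, dtype=bool)
    skap_negative[neg_idx] = True
    skap_member = rng.integers(0, 2, cfg.n_pairs)

    spindle_center = cfg.spindle_center_offset_um * np.array(
        [np.cos(theta0), np.sin(theta0), 0.0]
    )
    D = cfg.pole_distance_um
    rho0 = D * (r0 - 1.0) / (2.0 * (r0 + 1.0))

    anaphase_frame: int | None = None
    if cfg.anaphase_at_s is not None:
        hits = np.flatnonzero(times >= cfg.anaphase_at_s - 1e-9)
        anaphase_frame = int(hits[0]) if hits.size else None

    rows: list[tuple] = []
    r_true_t = np.empty(n_frames)
    pole_ref_t = np.empty((n_frames, 3))
    pole_other_t = np.empty((n_frames, 3))
    plate_t = np.empty((n_frames, 3))
    rot_t = np.empty(n_frames)
    sep_t = np.empty(n_frames)
    sis_ref_t = np.empty((n_frames, cfg.n_pairs, 3))
    sis_other_t = np.empty((n_frames, cfg.n_pairs, 3))

    noise = (
        rng.normal(0.0, cfg.noise_sigma_um, size=(n_frames, 2 * cfg.n_pairs
                                                  + len(ref_levels) + len(other_levels) + 2, 3))
        if cfg.noise_sigma_um > 0
        else np.zeros((n_frames, 2 * cfg.n_pairs + len(ref_levels) + len(other_levels) + 2, 3))
    )

    for k, t in enumerate(times):
        theta = theta0 + omega * t
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        e1 = np.array([-np.sin(theta), np.cos(theta), 0.0])
        e2 = np.array([0.0, 0.0, 1.0])
        basis = np.stack([u, e1, e2])  # rows

        pole_ref = spindle_center + (D / 2.0) * u
        pole_other = spindle_center - (D / 2.0) * u

        rho = rho0 if cfg.centering_tau_s is None else rho0 * np.exp(-t / cfg.centering_tau_s)
        L1 = D / 2.0 + rho  # distance from the reference pole to the plate
        r_true_t[k] = (D / 2.0 + rho) / (D / 2.0 - rho)
        plate = pole_ref - L1 * u

        if anaphase_frame is not None and k > anaphase_frame:
            ramp = 1.0 + (t - times[anaphase_frame]) / 15.0
            sep = min(cfg.inter_kt_um * ramp, 4.0)
            osc_t = times[anaphase_frame]
        else:
            sep = cfg.inter_kt_um
            osc_t = t
        a_p = cfg.osc_amplitude_um * np.sin(2.0 * np.pi * osc_t / cfg.osc_period_s + osc_phase)

        centers = plate[None, :] + np.outer(a_p, u) + np.outer(q1, e1) + np.outer(q2, e2)
        sis_ref = centers + (sep / 2.0) * u
        sis_other = centers - (sep / 2.0) * u

        pole_ref_t[k], pole_other_t[k], plate_t[k] = pole_ref, pole_other, plate
        rot_t[k] = np.rad2deg(omega * t)
        sep_t[k] = sep
        sis_ref_t[k], sis_other_t[k] = sis_ref, sis_other

        ni = 0
        for levels, pole, off in ((ref_levels, pole_ref, off_ref),
                                  (other_levels, pole_other, off_other)):
            for lvl, o in zip(levels, off):
                p = pole + o @ basis + noise[k, ni]
                rows.append((cell_id, k, t, Channel.CENTRIOLE.value, *p, lvl))
                ni += 1
        for p in sis_ref:
            rows.append((cell_id, k, t, Channel.KT_INNER.value, *(p + noise[k, ni]), _KT_INTENSITY))
            ni += 1
        for p in sis_other:
            rows.append((cell_id, k, t, Channel.KT_INNER.value, *(p + noise[k, ni]), _KT_INTENSITY))
            ni += 1
        for sgn in (+1.0, -1.0):
            p = sgn * cfg.cell_half_length_um * u + noise[k, ni]
            rows.append((cell_id, k, t, Channel.CORTEX.value, *p, 1.0))
            ni += 1

    detections = pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))
    series = CellSeries(
        cell_id=cell_id,
        detections=detections,
        dt_s=cfg.dt_s,
        config_label=cfg.config_label,
        group_label="sim",
        anaphase_frame=anaphase_frame,
    )

    # cleavage at the plate/axis intersection of the anaphase (or last) frame,
    # splitting the cell axis (cell center = origin, half-length h)
    kf = anaphase_frame if anaphase_frame is not None else n_frames - 1
    u_f = (pole_ref_t[kf] - pole_other_t[kf])
    u_f = u_f / np.linalg.norm(u_f)
    s_int = float(plate_t[kf] @ u_f)  # signed axis coordinate from the cell center
    h = cfg.cell_half_length_um
    truth = TrueCellParams(
        cell_id=cell_id,
        times_s=times,
        r_true=r_true_t,
        pole_ref=pole_ref_t,
        pole_other=pole_other_t,
        plate_point=plate_t,
        rotation_deg=rot_t,
        inter_kt_um=sep_t,
        sister_ref=sis_ref_t,
        sister_other=sis_other_t,
        delta_true_um=cfg.delta_um,
        anaphase_frame=anaphase_frame,
        daughter_size_ref=h - s_int,
        daughter_size_other=h + s_int,
        skap_negative_pairs=skap_negative,
        skap_negative_member=skap_member,
    )
    return series, truth


def simulate_cohort(cfg: SimConfig) -> tuple[list[CellSeries], list[TrueCellParams]]:
    """Simulate cfg.n_cells independent cells (per-cell seeds derived from cfg.seed)."""
    out = [simulate_cell(cfg, i) for i in range(cfg.n_cells)]
    return [c for c, _ in out], [t for _, t in out]


def simulate_fixed_snapshot(cfg: SimConfig, index: int = 0) -> tuple[CellSeries, TrueCellParams]:
    """One fixed-cell frame with inner + outer kinetochore and attachment markers.

    Outer-kinetochore (HEC1) points sit ``delta_um`` outward (poleward) of
    each inner point along the sister axis, so halving the outer–outer
    minus inner–inner distance difference recovers delta exactly in the
    noiseless case. Attachment-marker (SKAP) intensity is bimodal: in each
    ground-truth negative pair one randomly chosen sister carries the low
    level (10x below the positive level).
    """
    one_frame = replace(cfg, duration_s=cfg.dt_s * 1.0, anaphase_at_s=None,
                        osc_amplitude_um=cfg.osc_amplitude_um)
    rng = _cell_rng(cfg.seed, index + 1_000_000)  # independent stream from the live sim
    series, truth = simulate_cell(replace(one_frame, n_cells=1), index)
    # keep only frame 0 and augment with outer-KT / attachment channels
    det = series.detections
    det = det[det["frame"] == 0].reset_index(drop=True)
    k = 0
    u = truth.pole_ref[k] - truth.pole_other[k]
    u = u / np.linalg.norm(u)
    extra = []
    t0 = float(truth.times_s[k])
    nse = (lambda: rng.normal(0.0, cfg.noise_sigma_um, 3)) if cfg.noise_sigma_um > 0 else (lambda: np.zeros(3))
    for p_idx in range(cfg.n_pairs):
        inner_ref = truth.sister_ref[k, p_idx]
        inner_other = truth.sister_other[k, p_idx]
        outer_ref = inner_ref + cfg.delta_um * u + nse()
        outer_other = inner_other - cfg.delta_um * u + nse()
        extra.append((series.cell_id, 0, t0, Channel.KT_OUTER.value, *outer_ref, _KT_INTENSITY))
        extra.append((series.cell_id, 0, t0, Channel.KT_OUTER.value, *outer_other, _KT_INTENSITY))
        neg = truth.skap_negative_pairs[p_idx]
        member = truth.skap_negative_member[p_idx]
        for m_idx, inner in enumerate((inner_ref, inner_other)):
            lo = neg and (m_idx == member)
            level = 100.0 if lo else 1000.0
            level *= 1.0 + 0.05 * rng.standard_normal()
            extra.append((series.cell_id, 0, t0, Channel.ATTACH_MARK.value,
                          *(inner + nse()), max(level, 0.0)))
    det = pd.concat([det, pd.DataFrame(extra, columns=list(DETECTION_COLUMNS))],
                    ignore_index=True)
    snapshot = CellSeries(
        cell_id=series.cell_id,
        detections=det,
        dt_s=cfg.dt_s,
        config_label=cfg.config_label,
        group_label="fixed",
        anaphase_frame=None,
    )
    return snapshot, truth


def truth_to_frame(truths: list[TrueCellParams]) -> pd.DataFrame:
    """Long-format ground-truth table (one row per cell and frame)."""
    rows = []
    for t in truths:
        for k in range(len(t.times_s)):
            rows.append(
                {
                    "cell_id": t.cell_id,
                    "frame": k,
                    "time_s": t.times_s[k],
                    "r_true": t.r_true[k],
                    "rotation_deg": t.rotation_deg[k],
                    "inter_kt_um": t.inter_kt_um[k],
                    "delta_true_um": t.delta_true_um,
                    "anaphase_frame": -1 if t.anaphase_frame is None else t.anaphase_frame,
                    "daughter_size_ref": t.daughter_size_ref,
                    "daughter_size_other": t.daughter_size_other,
                    "daughter_ratio": t.daughter_ratio,
                    "n_skap_negative_pairs": int(t.skap_negative_pairs.sum()),
                }
            )
    return pd.DataFrame(rows)
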