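"""End-to-end per-cell analysis and cohort summarization.

``analyze_cell`` turns one :class:`CellSeries` of labeled point detections
into per-frame plate geometry (half-spindle ratio R, spindle-center
offset), sister-pair kinetics (inter-kinetochore distances, oscillation
autocorrelation and half-period), and phenotype calls (anaphase onset,
spindle rotation, attachment-marker status, intra-kinetochore δ when an
outer marker is present). ``analyze_cohort`` aggregates cells into
per-condition summaries, anaphase-aligned centering trajectories and the
statistical test battery against a control condition.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import geometry as geo
from . import kinetics as kin
from . import phenotypes as phe
from . import stats as cst
from .model import AnalysisConfig, CellSeries, Channel

__all__ = ["CellResult", "CohortSummary", "analyze_cell", "analyze_cohort"]

log = logging.getLogger(__name__)


@dataclass
class CellResult:
    cell_id: str
    condition: str
    group: str
    n_frames: int
    geometry_by_frame: dict[int, geo.PlateGeometry]
    r_by_frame: np.ndarray  # indexed by frame number, NaN where missing
    offset_by_frame: np.ndarray
    n_pairs: int
    n_unpaired: int
    mean_inter_kt_um: float
    metaphase_R: float
    anaphase_R: float | None
    anaphase_frame: int | None
    ac_profile: kin.ACProfile | None
    half_period_s: float | None
    ac_depth: float | None
    rotation: phe.RotationCall | None
    skap_positive: bool | None
    skap_negative_fraction: float | None
    delta_um: float | None
    division: phe.DivisionCall | None = None

    def metrics_row(self) -> dict[str, Any]:
        rot = self.rotation
        return {
            "cell_id": self.cell_id,
            "condition": self.condition,
            "group": self.group,
            "n_frames": self.n_frames,
            "n_pairs": self.n_pairs,
            "metaphase_R": self.metaphase_R,
            "anaphase_R": np.nan if self.anaphase_R is None else self.anaphase_R,
            "anaphase_frame": -1 if self.anaphase_frame is None else self.anaphase_frame,
            "mean_inter_kt_um": self.mean_inter_kt_um,
            "half_period_s": np.nan if self.half_period_s is None else self.half_period_s,
            "ac_depth": np.nan if self.ac_depth is None else self.ac_depth,
            "max_xy_angle_deg": np.nan if rot is None else rot.max_xy_angle_deg,
            "rotating": False if rot is None else rot.rotating,
            "division_ratio": np.nan if self.division is None else self.division.ratio,
            "asymmetric_division": False if self.division is None else self.division.asymmetric,
            "skap_positive_cell": False if self.skap_positive is None else self.skap_positive,
            "skap_negative_fraction": (
                np.nan if self.skap_negative_fraction is None else self.skap_negative_fraction
            ),
            "delta_um": np.nan if self.delta_um is None else self.delta_um,
            "mean_center_offset_um": float(np.nanmean(self.offset_by_frame))
            if np.isfinite(self.offset_by_frame).any() else np.nan,
        }


@dataclass
class CohortSummary:
    """Per-condition cohort summary plus the cross-condition test battery."""

    conditions: dict[str, dict[str, Any]]
    test_results: list[cst.TestResult]
    config: AnalysisConfig
    control_condition: str | None = None

    def to_dict(self) -> dict[str, Any]:
        conds = {}
        for name, block in self.conditions.items():
            block = dict(block)
            traj = block.get("trajectory")
            if traj is not None:
                block["trajectory"] = [
                    {
                        "time_to_anaphase_s": r.time_to_anaphase_s,
                        "median_R": r.median_R,
                        "ci_lo": r.ci_lo,
                        "ci_hi": r.ci_hi,
                        "n_cells": r.n_cells,
                    }
                    for r in traj
                ]
            conds[name] = block
        return {
            "conditions": conds,
            "control_condition": self.control_condition,
            "tests": [
                {
                    "name": t.name,
                    "groups": list(t.n),
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "alternative": t.alternative,
                    "method": t.method,
                    "comparison": getattr(t, "comparison", ""),
                }
                for t in self.test_results
            ],
            "analysis_config": self.config.to_dict(),
            "p_values_are_raw": True,
        }


def _frame_geometry(cell: CellSeries, config: AnalysisConfig) -> tuple[
    dict[int, geo.PlateGeometry], np.ndarray, np.ndarray
]:
    frames = cell.frames
    n_max = max(frames) + 1
    r = np.full(n_max, np.nan)
    offset = np.full(n_max, np.nan)
    out: dict[int, geo.PlateGeometry] = {}
    for f in frames:
        cents = cell.frame_detections(f, Channel.CENTRIOLE)
        kts = cell.frame_points(f, Channel.KT_INNER)
        if len(cents) < 2 or len(kts) < 3:
            continue
        try:
            poles = geo.cluster_poles(
                cents[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                cents["intensity"].to_numpy(dtype=float),
            )
            ref = geo.assign_reference_pole(poles, cell.config_label)
            plane = geo.fit_plate_plane(kts)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                g = geo.plate_metrics(plane, poles, ref)
        except geo.GeometryError as err:
            log.warning("cell %s frame %d: %s", cell.cell_id, f, err)
            continue
        out[f] = g
        r[f] = g.R
        cortex = cell.frame_points(f, Channel.CORTEX)
        if len(cortex) >= 2:
            try:
                offset[f] = geo.spindle_center_offset(poles, cortex)
            except geo.GeometryError:
                pass
    return out, r, offset


def _snapshot_extras(cell: CellSeries, pairs: list[kin.SisterPair], config: AnalysisConfig,
                     frame: int) -> tuple[float | None, bool | None, float | None]:
    """Intra-KT δ and attachment-marker call from a frame carrying extra channels."""
    outer = cell.frame_points(frame, Channel.KT_OUTER)
    attach = cell.frame_detections(frame, Channel.ATTACH_MARK)
    delta = None
    if len(outer) >= 2 and pairs:
        deltas = []
        for p in pairs:
            pa = p.track_a.position_at(frame)
            pb = p.track_b.position_at(frame)
            if pa is None or pb is None:
                continue
            oa = outer[np.argmin(np.linalg.norm(outer - pa, axis=1))]
            ob = outer[np.argmin(np.linalg.norm(outer - pb, axis=1))]
            deltas.append(kin.intra_kt_delta(float(np.linalg.norm(pa - pb)),
                                             float(np.linalg.norm(oa - ob))))
        if deltas:
            delta = float(np.mean(deltas))
    skap_call = skap_frac = None
    if len(attach) >= 2 and pairs:
        apos = attach[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        aint = attach["intensity"].to_numpy(dtype=float)
        pair_int = []
        for p in pairs:
            pa = p.track_a.position_at(frame)
            pb = p.track_b.position_at(frame)
            if pa is None or pb is None:
                continue
            ia = aint[np.argmin(np.linalg.norm(apos - pa, axis=1))]
            ib = aint[np.argmin(np.linalg.norm(apos - pb, axis=1))]
            pair_int.append((float(ia), float(ib)))
        if pair_int:
            skap_call, skap_frac, _ = phe.classify_skap_cell(
                pair_int,
                neg_rel_threshold=config.skap_negative_rel_threshold,
                frac_threshold=config.skap_negative_pair_fraction,
            )
    return delta, skap_call, skap_frac


def analyze_cell(cell: CellSeries, config: AnalysisConfig | None = None) -> CellResult:
    config = config or AnalysisConfig()
    geometry, r_by_frame, offset = _frame_geometry(cell, config)

    from .linking import link_tracks

    tracks = link_tracks(cell.detections, config.max_step_um, config.max_gap_frames,
                         channel=Channel.KT_INNER).tracks
    pair_set = kin.pair_tracks(tracks, config.pairing_gate_um)
    pairs = pair_set.pairs

    frames = np.array(cell.frames)
    inter = (
        np.vstack([kin.inter_kt_series(p, frames) for p in pairs]) if pairs else np.empty((0, len(frames)))
    )
    pre_anaphase_mask = np.ones(len(frames), dtype=bool)

    detected = phe.detect_anaphase_onset(
        cell, pairs,
        fold=config.anaphase_fold,
        baseline_frames=config.anaphase_baseline_frames,
        sustain_frames=config.anaphase_sustain_frames,
    )
    anaphase = detected if detected is not None else cell.anaphase_frame
    if anaphase is not None:
        pre_anaphase_mask = frames < anaphase

    mean_inter = float(np.nanmean(inter[:, pre_anaphase_mask])) if pairs else np.nan

    # oscillation profile: per-pair AC over metaphase frames, averaged per cell
    profiles = []
    for p in pairs:
        series = kin.axis_position_series(p, geometry, frames)[pre_anaphase_mask]
        try:
            profiles.append(kin.oscillation_autocorrelation(series, cell.dt_s,
                                                            config.ac_max_lag_s))
        except ValueError:
            continue
    profile = kin.average_profiles(profiles) if profiles else None
    hp = depth = None
    if profile is not None:
        hp, depth = kin.half_period(profile, config.ac_min_depth)

    rotation = None
    if len(geometry) >= 2:
        try:
            rotation = phe.detect_rotation(geometry, config.rotation_threshold_deg)
        except ValueError as err:
            log.warning("cell %s: rotation call failed: %s", cell.cell_id, err)

    meta_R, ana_R = (np.nan, None)
    if np.isfinite(r_by_frame).any():
        meta_R, ana_R = cst.metaphase_R_selection(r_by_frame, anaphase,
                                                  k_first=config.metaphase_frames)

    f0 = int(frames[0])
    delta, skap_call, skap_frac = _snapshot_extras(cell, pairs, config, f0)

    return CellResult(
        cell_id=cell.cell_id,
        condition=cell.config_label.value,
        group=cell.group_label,
        n_frames=len(frames),
        geometry_by_frame=geometry,
        r_by_frame=r_by_frame,
        offset_by_frame=offset,
        n_pairs=len(pairs),
        n_unpaired=pair_set.n_unpaired,
        mean_inter_kt_um=mean_inter,
        metaphase_R=meta_R,
        anaphase_R=ana_R,
        anaphase_frame=anaphase,
        ac_profile=profile,
        half_period_s=hp,
        ac_depth=depth,
        rotation=rotation,
        skap_positive=skap_call,
        skap_negative_fraction=skap_frac,
        delta_um=delta,
    )


def analyze_cohort(
    cells: Sequence[CellSeries],
    config: AnalysisConfig | None = None,
    daughter_sizes: Mapping[str, tuple[float, float]] | None = None,
    control_condition: str | None = None,
) -> tuple[pd.DataFrame, CohortSummary]:
    """Analyze every cell and summarize per condition (= config label).

    ``daughter_sizes`` optionally maps cell_id to the two measured daughter
    sizes; the Mann–Whitney/Welch battery compares each condition's
    metaphase R against ``control_condition`` (defaults to C22 or WT when
    present).
    """
    config = config or AnalysisConfig()
    results = [analyze_cell(c, config) for c in cells]
    if daughter_sizes:
        for res in results:
            if res.cell_id in daughter_sizes:
                a, b = daughter_sizes[res.cell_id]
                res.division = phe.classify_division(a, b, config.division_ratio_threshold)

    metrics = pd.DataFrame([r.metrics_row() for r in results])

    conditions: dict[str, dict[str, Any]] = {}
    by_cond: dict[str, list[CellResult]] = {}
    for r in results:
        by_cond.setdefault(r.condition, []).append(r)

    dt_s = cells[0].dt_s if cells else 1.0
    for cond, group in sorted(by_cond.items()):
        r_vals = [g.metaphase_R for g in group if np.isfinite(g.metaphase_R)]
        block: dict[str, Any] = {"n_cells": len(group)}
        if r_vals:
            med, frac_out, frac_hi = cst.ratio_distribution_summary(
                r_vals, config.r_lo, config.r_hi
            )
            block.update(median_R=med, frac_outside=frac_out, frac_above_115=frac_hi)
        ana_vals = [g.anaphase_R for g in group if g.anaphase_R is not None]
        if ana_vals:
            med_a, frac_out_a, frac_hi_a = cst.ratio_distribution_summary(
                ana_vals, config.r_lo, config.r_hi
            )
            block.update(median_R_anaphase=med_a, frac_outside_anaphase=frac_out_a,
                         frac_above_115_anaphase=frac_hi_a)
        rot = [g.rotation.rotating for g in group if g.rotation is not None]
        if rot:
            block["frac_rotating"] = float(np.mean(rot))
        div = [g.division.asymmetric for g in group if g.division is not None]
        if div:
            block["frac_asymmetric_division"] = float(np.mean(div))
        skap = [g.skap_positive for g in group if g.skap_positive is not None]
        if skap:
            block["frac_skap_positive"] = float(np.mean(skap))
        hp_vals = [g.half_period_s for g in group if g.half_period_s is not None]
        if hp_vals:
            block["median_half_period_s"] = float(np.median(hp_vals))
        delta_vals = [g.delta_um for g in group if g.delta_um is not None]
        if delta_vals:
            block["mean_delta_um"] = float(np.mean(delta_vals))

        traj_cells = [(g.r_by_frame, g.anaphase_frame) for g in group
                      if g.anaphase_frame is not None and np.isfinite(g.r_by_frame).any()]
        if len(traj_cells) >= 3:
            block["trajectory"] = cst.anaphase_aligned_trajectories(
                [t[0] for t in traj_cells],
                [t[1] for t in traj_cells],
                dt_s,
                n_boot=config.n_boot,
                seed=config.seed,
            )
        conditions[cond] = block

    if control_condition is None:
        for candidate in ("C22", "WT"):
            if candidate in by_cond:
                control_condition = candidate
                break

    tests: list[cst.TestResult] = []
    if control_condition is not None:
        ctrl = [g.metaphase_R for g in by_cond[control_condition]
                if np.isfinite(g.metaphase_R)]
        for cond, group in sorted(by_cond.items()):
            if cond == control_condition:
                continue
            other = [g.metaphase_R for g in group if np.isfinite(g.metaphase_R)]
            if len(ctrl) >= 2 and len(other) >= 2:
                for test in ("mann_whitney_u", "welch_t"):
                    t = cst.compare_groups(other, ctrl, test)
                    tests.append(
                        dataclasses.replace(t, comparison=f"{cond} vs {control_condition}")
                    )

    summary = CohortSummary(
        conditions=conditions,
        test_results=tests,
        config=config,
        control_condition=control_condition,
    )
    return metrics, summary
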