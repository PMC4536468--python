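"""Core data model for 3D spindle point-detection analysis.

Everything downstream of the microscope is represented as labeled 3D point
detections in micrometres: centrioles (centrin marker), inner/outer
kinetochore markers (CENPA / HEC1), an attachment-maturity marker (SKAP) and
cell-cortex reference points. A :class:`CellSeries` holds the ordered frames
of one cell plus its metadata (centriole configuration, treatment group).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "ConfigLabel",
    "Detection",
    "CellSeries",
    "Track",
    "TrackSet",
    "AnalysisConfig",
    "DETECTION_COLUMNS",
]

#: Fixed column contract of the detection table (CSV header, comma-separated,
#: '.' decimal). Coordinates are metric (μm); voxel anisotropy is assumed to
#: be applied upstream.
DETECTION_COLUMNS = (
    "cell_id",
    "frame",
    "time_s",
    "channel",
    "x_um",
    "y_um",
    "z_um",
    "intensity",
)


class Channel(str, enum.Enum):
    """Fluorescence channel / point label.

    CENTRIOLE  - centrin marker (spindle poles; grandmother brightest)
    KT_INNER   - inner-kinetochore marker (CENPA)
    KT_OUTER   - outer-kinetochore marker (HEC1)
    ATTACH_MARK- attachment-maturity marker (SKAP)
    CORTEX     - cell-cortex reference point (phase contrast)
    """

    CENTRIOLE = "CENTRIOLE"
    KT_INNER = "KT_INNER"
    KT_OUTER = "KT_OUTER"
    ATTACH_MARK = "ATTACH_MARK"
    CORTEX = "CORTEX"


class ConfigLabel(str, enum.Enum):
    """Centriole configuration of a cell: 2:2 (wild type), 2:1 or 1:1."""

    WT = "WT"
    C22 = "C22"
    C21 = "C21"
    C11 = "C11"


@dataclass(frozen=True)
class Detection:
    """One labeled 3D point with intensity at a timepoint."""

    cell_id: str
    frame: int
    time_s: float
    channel: Channel
    pos: np.ndarray  # shape (3,), μm
    intensity: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"detection position must be a finite 3-vector, got {pos!r}")
        object.__setattr__(self, "pos", pos)
        if self.frame < 0:
            raise ValueError("frame must be >= 0")
        if self.time_s < 0:
            raise ValueError("time_s must be >= 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")


@dataclass
class CellSeries:
    """Ordered frames of detections for one cell, plus metadata.

    ``detections`` is a tidy DataFrame with the :data:`DETECTION_COLUMNS`
    schema, sorted by (frame, channel). ``dt_s`` is the nominal sampling
    interval; frames are 0-based and (frame -> time_s) must be strictly
    increasing.
    """

    cell_id: str
    detections: pd.DataFrame
    dt_s: float
    config_label: ConfigLabel = ConfigLabel.WT
    group_label: str = ""
    anaphase_frame: int | None = None

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if len(self.detections) == 0:
            raise ValueError("CellSeries needs at least one frame of detections")
        ft = (
            self.detections[["frame", "time_s"]]
            .drop_duplicates("frame")
            .sort_values("frame")
        )
        if not np.all(np.diff(ft["time_s"].to_numpy()) > 0) and len(ft) > 1:
            raise ValueError(f"cell {self.cell_id}: time_s must increase strictly with frame")
        if self.anaphase_frame is not None and self.anaphase_frame not in set(ft["frame"]):
            raise ValueError("anaphase_frame does not index an existing frame")

    @property
    def frames(self) -> list[int]:
        return sorted(self.detections["frame"].unique().tolist())

    def frame_detections(self, frame: int, channel: Channel | None = None) -> pd.DataFrame:
        sub = self.detections[self.detections["frame"] == frame]
        if channel is not None:
            sub = sub[sub["channel"] == channel.value]
        return sub

    def frame_points(self, frame: int, channel: Channel) -> np.ndarray:
        """(n, 3) array of positions for one frame and channel."""
        sub = self.frame_detections(frame, channel)
        return sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    def frame_time(self, frame: int) -> float:
        sub = self.detections[self.detections["frame"] == frame]
        if len(sub) == 0:
            raise KeyError(f"frame {frame} not present")
        return float(sub["time_s"].iloc[0])


@dataclass
class Track:
    """One particle track: ordered (frame, pos, intensity) samples, one per frame."""

    channel: Channel
    frames: np.ndarray  # (n,) int, strictly increasing
    positions: np.ndarray  # (n, 3) μm
    intensities: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions length mismatch")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("track frames must be strictly increasing (<=1 sample/frame)")

    def __len__(self) -> int:
        return len(self.frames)

    def position_at(self, frame: int) -> np.ndarray | None:
        idx = np.flatnonzero(self.frames == frame)
        return self.positions[idx[0]] if idx.size else None


@dataclass
class TrackSet:
    tracks: list[Track]
    max_step_um: float
    max_gap_frames: int

    @property
    def n_samples(self) -> int:
        return sum(len(t) for t in self.tracks)


def _config_fields() -> dict[str, Any]:
    return {f.name: f for f in dataclasses.fields(AnalysisConfig)}


@dataclass
class AnalysisConfig:
    """All downstream tunables, serializable to/from YAML or JSON.

    Defaults encode the operational definitions used throughout: the strict
    1.2 daughter-size ratio for an asymmetric division, the 90° net-rotation
    call, the 0.85/1.15 half-spindle-ratio boundaries, and the >30%
    marker-negative rule for partially unstable attachments.
    """

    # track linking
    max_step_um: float = 1.0
    max_gap_frames: int = 1
    # sister pairing
    pairing_gate_um: float = 2.0
    # oscillation analysis
    ac_max_lag_s: float = 150.0
    ac_min_depth: float = -0.1
    # anaphase-onset detection
    anaphase_fold: float = 1.5
    anaphase_baseline_frames: int = 3
    anaphase_sustain_frames: int = 2
    # phenotype thresholds
    rotation_threshold_deg: float = 90.0
    division_ratio_threshold: float = 1.2
    skap_negative_rel_threshold: float = 0.3
    skap_negative_pair_fraction: float = 0.3
    minus_end_fold: float = 1.5
    # ratio-distribution boundaries
    r_lo: float = 0.85
    r_hi: float = 1.15
    metaphase_frames: int = 3
    # bootstrap
    n_boot: int = 1000
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = _config_fields()
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown AnalysisConfig keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def detections_to_frame(detections: Iterable[Detection]) -> pd.DataFrame:
    """Build a schema-conforming DataFrame from Detection objects."""
    rows = [
        {
            "cell_id": d.cell_id,
            "frame": d.frame,
            "time_s": d.time_s,
            "channel": d.channel.value,
            "x_um": d.pos[0],
            "y_um": d.pos[1],
            "z_um": d.pos[2],
            "intensity": d.intensity,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=list(DETECTION_COLUMNS))
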