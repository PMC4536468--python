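"""Readers and writers for detection tables, metadata, configs and reports.

The detection table schema is a fixed CSV contract::

    cell_id,frame,time_s,channel,x_um,y_um,z_um,intensity

comma-separated, '.' decimal, header required. Coordinates are metric (μm);
any voxel anisotropy is applied upstream.
"""

from __future__ import annotations

import json
import pathlib
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import AnalysisConfig, Channel, ConfigLabel, DETECTION_COLUMNS

__all__ = [
    "SchemaError",
    "read_detections",
    "write_detections",
    "read_metadata",
    "load_config",
    "save_config",
    "write_report",
    "read_report",
]


class SchemaError(ValueError):
    """Input file does not match the documented column contract."""


_NUMERIC = {"frame": int, "time_s": float, "x_um": float, "y_um": float,
            "z_um": float, "intensity": float}
_CHANNELS = {c.value for c in Channel}


def read_detections(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a detection CSV, validating schema, units and channel labels.

    Returns the table typed and in file row order. Raises
    :class:`SchemaError` naming the first missing column, and ValueError
    with the 1-based data line number on a non-numeric coordinate.
    """
    path = pathlib.Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in DETECTION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"detection table {path.name!r} is missing column {col!r}")
    df = df[list(DETECTION_COLUMNS)]
    out = df.copy()
    for col, typ in _NUMERIC.items():
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2  # header is line 1
            raise ValueError(
                f"{path.name}:{line}: non-numeric value {df[col][converted.isna()].iloc[0]!r} "
                f"in column {col!r}"
            )
        out[col] = converted.astype(typ)
    bad_chan = ~df["channel"].isin(_CHANNELS)
    if bad_chan.any():
        line = int(np.flatnonzero(bad_chan.to_numpy())[0]) + 2
        raise ValueError(f"{path.name}:{line}: unknown channel {df['channel'][bad_chan].iloc[0]!r}")
    if len(out):
        if (out["frame"] < 0).any() or (out["time_s"] < 0).any():
            raise ValueError("frame and time_s must be >= 0")
        if (out["intensity"] < 0).any():
            raise ValueError("intensity must be >= 0")
        coords = out[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinate in detection table")
    return out


def write_detections(df: pd.DataFrame, path: str | pathlib.Path) -> None:
    df = df[list(DETECTION_COLUMNS)]
    df.to_csv(path, index=False, float_format="%.12g")


def read_metadata(path: str | pathlib.Path) -> pd.DataFrame:
    """Read per-cell metadata CSV: cell_id, config_label, group_label."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("cell_id", "config_label", "group_label"):
        if col not in df.columns:
            raise SchemaError(f"metadata table is missing column {col!r}")
    bad = ~df["config_label"].isin({c.value for c in ConfigLabel})
    if bad.any():
        raise ValueError(f"unknown config_label {df['config_label'][bad].iloc[0]!r}")
    return df


def load_config(path: str | pathlib.Path) -> AnalysisConfig:
    """Load an AnalysisConfig from YAML or JSON (by extension; YAML reads both)."""
    path = pathlib.Path(path)
    text = path.read_text()
    data: Mapping[str, Any]
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    return AnalysisConfig.from_dict(data)


def save_config(cfg: AnalysisConfig, path: str | pathlib.Path) -> None:
    path = pathlib.Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(cfg.to_json() + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(summary: "Mapping[str, Any]", metrics: pd.DataFrame,
                 out_dir: str | pathlib.Path, stem: str = "cohort") -> tuple[pathlib.Path, pathlib.Path]:
    """Write the per-cell metrics CSV and the cohort summary JSON.

    Reals are serialized to 12 significant digits so that re-reading
    reproduces them to that precision; integers round-trip exactly.
    Returns (metrics_path, summary_path).
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metrics_path = out_dir / f"{stem}_metrics.csv"
    summary_path = out_dir / f"{stem}_summary.json"
    metrics.to_csv(metrics_path, index=False, float_format="%.12g")
    payload = _jsonify(dict(summary))
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
    return metrics_path, summary_path


def read_report(out_dir: str | pathlib.Path, stem: str = "cohort") -> tuple[pd.DataFrame, dict]:
    out_dir = pathlib.Path(out_dir)
    metrics = pd.read_csv(out_dir / f"{stem}_metrics.csv")
    summary = json.loads((out_dir / f"{stem}_summary.json").read_text())
    return metrics, summary
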