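"""Gated greedy nearest-neighbor track linking and cell assembly.

The linker is plumbing for detection tables that lack track identities: a
per-frame greedy nearest-neighbor assignment with a hard distance gate and
an optional frame gap. Ties are broken by input row order.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import CellSeries, Channel, ConfigLabel, Track, TrackSet

__all__ = ["link_tracks", "assemble_cells"]

log = logging.getLogger(__name__)


def link_tracks(
    table: pd.DataFrame,
    max_step_um: float,
    max_gap_frames: int = 0,
    channel: Channel | None = None,
) -> TrackSet:
    """Link detections of one cell into tracks.

    Frame by frame, each open track claims the nearest unclaimed detection
    within ``max_step_um`` of its last position, closest links first;
    leftovers seed new tracks. A track stays open across up to
    ``max_gap_frames`` missing frames. Every detection ends up in exactly
    one track and no link exceeds the gate.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be > 0")
    df = table
    if channel is not None:
        df = df[df["channel"] == channel.value]
    df = df.sort_values(["frame"], kind="stable").reset_index(drop=True)

    # open track state: (last_frame, last_pos, samples)
    open_tracks: list[dict] = []
    done: list[dict] = []
    for frame, sub in df.groupby("frame", sort=True):
        pos = sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        inten = sub["intensity"].to_numpy(dtype=float)
        chans = sub["channel"].to_numpy()
        n = len(sub)
        # retire tracks whose gap budget is exhausted
        still_open = []
        for tr in open_tracks:
            if frame - tr["last_frame"] > max_gap_frames + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        claimed = np.zeros(n, dtype=bool)
        if open_tracks and n:
            last = np.array([tr["last_pos"] for tr in open_tracks])
            dist = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            # candidate links sorted by (distance, track order, row order)
            order = sorted(
                ((dist[i, j], i, j) for i in range(len(open_tracks)) for j in range(n)
                 if dist[i, j] <= max_step_um),
                key=lambda t: (t[0], t[1], t[2]),
            )
            linked_tracks: set[int] = set()
            for d, i, j in order:
                if i in linked_tracks or claimed[j]:
                    continue
                tr = open_tracks[i]
                tr["samples"].append((int(frame), pos[j], inten[j]))
                tr["last_frame"] = int(frame)
                tr["last_pos"] = pos[j]
                linked_tracks.add(i)
                claimed[j] = True
        for j in np.flatnonzero(~claimed):
            open_tracks.append(
                {
                    "channel": chans[j],
                    "samples": [(int(frame), pos[j], inten[j])],
                    "last_frame": int(frame),
                    "last_pos": pos[j],
                }
            )
    done.extend(open_tracks)

    tracks = []
    for tr in done:
        frames = np.array([s[0] for s in tr["samples"]], dtype=int)
        positions = np.array([s[1] for s in tr["samples"]], dtype=float)
        intensities = np.array([s[2] for s in tr["samples"]], dtype=float)
        tracks.append(Track(Channel(tr["channel"]), frames, positions, intensities))
    tracks.sort(key=lambda t: (int(t.frames[0]), float(t.positions[0, 0])))
    ts = TrackSet(tracks=tracks, max_step_um=max_step_um, max_gap_frames=max_gap_frames)
    assert ts.n_samples == len(df), "linker must conserve detections"
    return ts


def assemble_cells(table: pd.DataFrame, metadata: pd.DataFrame) -> list[CellSeries]:
    """Group a detection table into one CellSeries per cell.

    ``metadata`` supplies config_label (and optionally group_label,
    anaphase_frame) per cell_id. dt_s is inferred as the median inter-frame
    interval. Cells without kinetochore detections are excluded with a
    warning.
    """
    meta = metadata.set_index("cell_id")
    cells: list[CellSeries] = []
    for cell_id, sub in table.groupby("cell_id", sort=True):
        sub = sub.sort_values(["frame"], kind="stable").reset_index(drop=True)
        if not (sub["channel"] == Channel.KT_INNER.value).any():
            log.warning("cell %s has no kinetochore detections; excluded", cell_id)
            continue
        if cell_id not in meta.index:
            raise KeyError(f"cell {cell_id!r} missing from metadata")
        row = meta.loc[cell_id]
        times = np.sort(sub.drop_duplicates("frame")["time_s"].to_numpy(dtype=float))
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        anaphase = row.get("anaphase_frame", None)
        if anaphase is not None and (pd.isna(anaphase) or anaphase == ""):
            anaphase = None
        cells.append(
            CellSeries(
                cell_id=str(cell_id),
                detections=sub,
                dt_s=dt,
                config_label=ConfigLabel(row["config_label"]),
                group_label=str(row.get("group_label", "")),
                anaphase_frame=int(anaphase) if anaphase is not None else None,
            )
        )
    return cells
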