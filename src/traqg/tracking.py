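"""Greedy nearest-centroid linking of per-cell measurements over time.

Automates what was classically done by hand for time-lapse nuclei: per
adjacent frame pair, mutually nearest centroids within ``max_disp_px``
are linked (ties broken deterministically by smaller label id), so the
linking is conservative — two cells whose swap would exceed the gate
terminate their tracks rather than swap identities.  A track unmatched
for more than ``gap_frames`` consecutive frames is closed as lost.  When
two new detections appear within the gate of a just-vanished track they
are recorded as daughters via ``parent_id`` (a simple, auditable
division heuristic, not a mitosis classifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pipeline import CellMeasurement

__all__ = ["TrackPoint", "Track", "link_tracks", "summarize_tracks", "tracks_to_frame"]


@dataclass
class TrackPoint:
    frame: int
    time_h: float
    measurement: CellMeasurement

    @property
    def centroid(self) -> tuple[float, float]:
        return self.measurement.centroid


@dataclass
class Track:
    track_id: int
    points: list[TrackPoint] = field(default_factory=list)
    parent_id: int | None = None
    status: Literal["complete", "lost", "merged"] = "complete"

    def __len__(self) -> int:
        return len(self.points)

    @property
    def last(self) -> TrackPoint:
        return self.points[-1]


def _mutual_nearest_pairs(
    heads: list[tuple[int, tuple[float, float]]],
    dets: list[tuple[int, tuple[float, float]]],
    max_disp: float,
) -> list[tuple[int, int]]:
    """Mutually-nearest (head idx, det idx) pairs within the gate.

    Nearest neighbours are computed with ties broken by smaller label
    id / track id, which makes the result independent of input order.
    """
    if not heads or not dets:
        return []
    hx = np.array([h[1] for h in heads])
    dx = np.array([d[1] for d in dets])
    dist = np.linalg.norm(hx[:, None, :] - dx[None, :, :], axis=2)
    # order detections (and heads) by id for deterministic argmin ties
    det_order = np.argsort([d[0] for d in dets], kind="stable")
    head_order = np.argsort([h[0] for h in heads], kind="stable")
    pairs = []
    for i in range(len(heads)):
        j = det_order[int(np.argmin(dist[i, det_order]))]
        i_back = head_order[int(np.argmin(dist[head_order, j]))]
        if i_back == i and dist[i, j] <= max_disp:
            pairs.append((i, int(j)))
    return pairs


def link_tracks(
    frames: Sequence[Sequence[CellMeasurement]],
    times_h: Sequence[float] | None = None,
    max_disp_px: float = 15.0,
    gap_frames: int = 1,
) -> list[Track]:
    """Link per-frame detections into tracks.

    ``max_disp_px`` defaults to 15 px, appropriate for 30-min frame
    intervals of slowly migrating adherent cells.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to link")
    if times_h is None:
        times_h = list(range(len(frames)))
    tracks: list[Track] = []
    # active: track index -> frames since last match
    active: dict[int, int] = {}
    just_lost: list[int] = []  # track indices that closed on the previous frame

    def new_track(frame: int, t: float, m: CellMeasurement, parent: int | None):
        tr = Track(track_id=len(tracks) + 1, parent_id=parent)
        tr.points.append(TrackPoint(frame, float(t), m))
        tracks.append(tr)
        active[len(tracks) - 1] = 0

    for m in sorted(frames[0], key=lambda m: m.label):
        new_track(0, times_h[0], m, None)

    for f in range(1, len(frames)):
        dets = sorted(frames[f], key=lambda m: m.label)
        det_list = [(m.label, m.centroid) for m in dets]
        head_idx = sorted(active.keys(), key=lambda i: tracks[i].track_id)
        heads = [(tracks[i].track_id, tracks[i].last.centroid) for i in head_idx]
        pairs = _mutual_nearest_pairs(heads, det_list, max_disp_px)
        matched_tracks = set()
        matched_dets = set()
        for hi, dj in pairs:
            ti = head_idx[hi]
            tracks[ti].points.append(TrackPoint(f, float(times_h[f]), dets[dj]))
            active[ti] = 0
            matched_tracks.add(ti)
            matched_dets.add(dj)
        # age out unmatched tracks
        newly_lost = []
        for ti in list(active.keys()):
            if ti in matched_tracks:
                continue
            active[ti] += 1
            if active[ti] > gap_frames:
                tracks[ti].status = "lost"
                newly_lost.append(ti)
                del active[ti]
        # new detections: possibly daughters of a recently vanished track
        vanished = newly_lost + just_lost
        for dj, m in enumerate(dets):
            if dj in matched_dets:
                continue
            parent = None
            cands = []
            for ti in vanished:
                d = float(
                    np.hypot(
                        m.centroid[0] - tracks[ti].last.centroid[0],
                        m.centroid[1] - tracks[ti].last.centroid[1],
                    )
                )
                if d <= max_disp_px:
                    cands.append((d, tracks[ti].track_id))
            if cands:
                parent = min(cands)[1]
            new_track(f, times_h[f], m, parent)
        just_lost = newly_lost

    return tracks


def summarize_tracks(
    tracks: Sequence[Track],
    n_frames: int | None = None,
    calibrated: bool = False,
) -> pd.DataFrame:
    """Per-frame population mean, SD and n across live tracks.

    Uses ``gsh_mM`` when ``calibrated`` else ``mean_ratio``.  Frames with
    no live track appear with n = 0 and NaN statistics (a marked gap,
    never interpolated).
    """
    points: dict[int, list[tuple[float, float]]] = {}
    for tr in tracks:
        for p in tr.points:
            v = p.measurement.gsh_mM if calibrated else p.measurement.mean_ratio
            if v is None:
                raise ValueError("calibrated summary requested but gsh_mM missing")
            points.setdefault(p.frame, []).append((p.time_h, float(v)))
    if n_frames is None:
        n_frames = max(points) + 1 if points else 0
    rows = []
    for f in range(n_frames):
        vals = points.get(f, [])
        if vals:
            t = vals[0][0]
            x = np.array([v for _, v in vals])
            rows.append(
                {
                    "frame": f,
                    "time_h": t,
                    "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                    "n": int(x.size),
                }
            )
        else:
            rows.append({"frame": f, "time_h": np.nan, "mean": np.nan, "sd": np.nan, "n": 0})
    return pd.DataFrame(rows, columns=["frame", "time_h", "mean", "sd", "n"])


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Long-format table of all track points (one row per cell per frame)."""
    rows = []
    for tr in tracks:
        for p in tr.points:
            m = p.measurement
            rows.append(
                {
                    "track_id": tr.track_id,
                    "parent_id": tr.parent_id if tr.parent_id is not None else 0,
                    "frame": p.frame,
                    "time_h": p.time_h,
                    "label": m.label,
                    "row": m.centroid[0],
                    "col": m.centroid[1],
                    "mean_ratio": m.mean_ratio,
                    "gsh_mM": m.gsh_mM if m.gsh_mM is not None else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id", "parent_id", "frame", "time_h", "label",
            "row", "col", "mean_ratio", "gsh_mM",
        ],
    )
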