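"""Link per-frame detections into tracks and apply exclusion rules.

Linking is deterministic greedy nearest-neighbour assignment frame to frame:
adequate at the sparse cell densities this pipeline targets, and fully
reproducible.  Exclusion then removes, for the whole observation window, any
cell that touched another cell (a merged component), reached the frame
border, or disappeared early (operationalised "washed away by the flow").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

log = logging.getLogger(__name__)

EXCLUSION_LOG_COLUMNS = ["cell_id", "reason"]


@dataclass
class _RawTrack:
    cell_id: int
    frames: list[int] = field(default_factory=list)
    t_min: list[float] = field(default_factory=list)
    xy: list[tuple[float, float]] = field(default_factory=list)
    touches_border: bool = False
    merged: bool = False

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    @property
    def last_xy(self) -> np.ndarray:
        return np.asarray(self.xy[-1])


def link_detections(detections: pd.DataFrame, max_step_um: float = 20.0,
                    gap_frames: int = 3, dt: float = 1.0) -> list[_RawTrack]:
    """Greedy nearest-neighbour linking of a detections table.

    Candidate links between live tracks and the current frame's detections
    are taken in order of increasing distance (ties by lowest cell_id), each
    link limited to ``max_step_um``.  Unmatched detections start new tracks;
    tracks unmatched for more than ``gap_frames`` frames are terminated.
    Assignment conflicts (a nearer track already claimed the detection) are
    logged, not raised.
    """
    required = {"frame", "x_um", "y_um"}
    if not required <= set(detections.columns):
        raise ValueError(f"detections table needs columns {sorted(required)}")
    has_flags = {"touches_border", "merged"} <= set(detections.columns)

    live: list[_RawTrack] = []
    done: list[_RawTrack] = []
    next_id = 0
    for frame in sorted(detections["frame"].unique()):
        frame = int(frame)
        sub = detections[detections["frame"] == frame]
        pts = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        flags = (sub[["touches_border", "merged"]].to_numpy(dtype=bool)
                 if has_flags else np.zeros((len(sub), 2), dtype=bool))

        # retire tracks that have been unmatched too long
        still = []
        for tr in live:
            (still if frame - tr.last_frame <= gap_frames else done).append(tr)
        live = still

        # candidate links, globally greedy
        cands = []
        for ti, tr in enumerate(live):
            d = np.hypot(*(pts - tr.last_xy).T)
            for di in np.flatnonzero(d <= max_step_um):
                cands.append((float(d[di]), tr.cell_id, ti, int(di)))
        cands.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, _cid, ti, di in cands:
            if ti in used_t or di in used_d:
                if di in used_d and ti not in used_t:
                    log.debug("frame %d: track %d lost detection %d to a nearer track",
                              frame, live[ti].cell_id, di)
                continue
            used_t.add(ti)
            used_d.add(di)
            tr = live[ti]
            tr.frames.append(frame)
            tr.t_min.append(frame * dt)
            tr.xy.append((pts[di, 0], pts[di, 1]))
            tr.touches_border |= bool(flags[di, 0])
            tr.merged |= bool(flags[di, 1])
        for di in range(len(pts)):
            if di not in used_d:
                tr = _RawTrack(cell_id=next_id)
                next_id += 1
                tr.frames.append(frame)
                tr.t_min.append(frame * dt)
                tr.xy.append((pts[di, 0], pts[di, 1]))
                tr.touches_border |= bool(flags[di, 0])
                tr.merged |= bool(flags[di, 1])
                live.append(tr)
    return sorted(done + live, key=lambda tr: tr.cell_id)


class EmptyCohortError(RuntimeError):
    """Every track was excluded; no cohort remains to analyse."""


def apply_exclusions(raw_tracks, observation_frames: int, dt: float = 1.0,
                     group_label: str = "group", flow_angle: float = 0.0,
                     gap_frames: int = 3) -> tuple[TrackSet, pd.DataFrame]:
    """Apply whole-track exclusion rules and build the analysis TrackSet.

    A track is excluded if any of its detections was merged with another
    cell (``touched_cell``), any reached the frame border (``exited_frame``),
    or it does not span frames ``0 .. observation_frames-1`` contiguously
    (``washed_away`` — early permanent disappearance).  Checks are applied
    in that order; the first violated rule names the reason.  Surviving
    tracks are re-zeroed so the position at t = 0 is the origin.

    Returns the TrackSet of included tracks and an exclusion log
    (``cell_id, reason``).  Raises :class:`EmptyCohortError` if nothing
    survives.
    """
    included: list[Track] = []
    log_rows = []
    for tr in raw_tracks:
        if tr.merged:
            reason = "touched_cell"
        elif tr.touches_border:
            reason = "exited_frame"
        elif (tr.frames[0] != 0 or tr.frames[-1] != observation_frames - 1
              or len(tr.frames) != observation_frames):
            reason = "washed_away"
        else:
            reason = None
        if reason is None:
            t = np.asarray(tr.t_min, dtype=float)
            xy = np.asarray(tr.xy, dtype=float)
            included.append(Track(tr.cell_id, t, xy - xy[0], complete=True))
        else:
            log_rows.append((tr.cell_id, reason))
    log_df = pd.DataFrame(log_rows, columns=EXCLUSION_LOG_COLUMNS)
    if not included:
        raise EmptyCohortError(
            f"all {len(list(raw_tracks))} tracks excluded "
            f"({log_df['reason'].value_counts().to_dict()})")
    return TrackSet(group_label, included, dt=dt, flow_angle=flow_angle), log_df
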