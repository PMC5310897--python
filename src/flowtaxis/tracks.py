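"""Track containers and CSV I/O.

A :class:`Track` is one cell's centroid trajectory sampled at a uniform frame
interval; a :class:`TrackSet` groups the tracks of one experimental condition
(shear level x genotype).  All positions are in micrometres, times in minutes.
The on-disk schema is a long-format CSV with columns
``group, cell_id, frame, t_min, x_um, y_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["group", "cell_id", "frame", "t_min", "x_um", "y_um"]

#: exclusion reasons recognised downstream
EXCLUSION_REASONS = ("touched_cell", "exited_frame", "washed_away")


@dataclass
class Track:
    """One cell's positions over time.

    Parameters
    ----------
    cell_id:
        Identifier unique within its group.
    t_min:
        Strictly increasing, uniformly spaced sample times in minutes.
    xy:
        ``(n, 2)`` array of positions in micrometres, ``x`` along the flow
        axis (image columns), ``y`` across it (image rows).
    complete:
        Whether the track spans the full observation window.
    exclusion_reason:
        ``None`` for included tracks, else one of
        ``touched_cell | exited_frame | washed_away``.
    """

    cell_id: object
    t_min: np.ndarray
    xy: np.ndarray
    complete: bool = True
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t_min.ndim != 1 or self.xy.shape != (self.t_min.size, 2):
            raise ValueError("xy must be (n, 2) matching t_min of length n")
        if self.t_min.size >= 2:
            steps = np.diff(self.t_min)
            if np.any(steps <= 0):
                raise ValueError("t_min must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("t_min must be uniformly spaced")
        if self.exclusion_reason is not None and self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion_reason {self.exclusion_reason!r}")

    @property
    def n_frames(self) -> int:
        return self.t_min.size

    @property
    def dt(self) -> float:
        if self.t_min.size < 2:
            raise ValueError("dt undefined for a single-point track")
        return float(self.t_min[1] - self.t_min[0])

    def rezeroed(self) -> "Track":
        """Copy with the first position shifted to the origin."""
        return Track(self.cell_id, self.t_min.copy(), self.xy - self.xy[0],
                     complete=self.complete, exclusion_reason=self.exclusion_reason)


@dataclass
class TrackSet:
    """Tracks of one experimental condition sharing a common time base."""

    group_label: str
    tracks: list[Track]
    dt: float
    flow_angle: float = 0.0  # radians; 0 = +x, flow left to right

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for tr in self.tracks:
            if tr.n_frames >= 2 and not np.isclose(tr.dt, self.dt, rtol=0, atol=1e-9):
                raise ValueError(f"track {tr.cell_id}: dt {tr.dt} != trackset dt {self.dt}")

    @property
    def n(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            frames = np.round(tr.t_min / self.dt).astype(int)
            rows.append(pd.DataFrame({
                "group": self.group_label,
                "cell_id": tr.cell_id,
                "frame": frames,
                "t_min": tr.t_min,
                "x_um": tr.xy[:, 0],
                "y_um": tr.xy[:, 1],
            }))
        if not rows:
            return pd.DataFrame(columns=TRACK_COLUMNS)
        return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def trackset_from_dataframe(df: pd.DataFrame, group_label: str | None = None,
                            flow_angle: float = 0.0) -> TrackSet:
    """Build a TrackSet from a long-format track table.

    If ``group_label`` is None the table must contain exactly one group.
    """
    if group_label is None:
        groups = df["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"expected one group, found {list(groups)}; pass group_label")
        group_label = str(groups[0])
    else:
        df = df[df["group"] == group_label]
        if df.empty:
            raise ValueError(f"no rows for group {group_label!r}")
    tracks = []
    for cid, sub in df.groupby("cell_id", sort=True):
        sub = sub.sort_values("t_min")
        tracks.append(Track(cid, sub["t_min"].to_numpy(),
                            sub[["x_um", "y_um"]].to_numpy()))
    dts = {tr.dt for tr in tracks if tr.n_frames >= 2}
    if not dts:
        raise ValueError("tracks too short to infer dt")
    if len(dts) > 1 and not np.allclose(sorted(dts), min(dts), atol=1e-9):
        raise ValueError("tracks have inconsistent frame intervals")
    return TrackSet(group_label, tracks, dt=min(dts), flow_angle=flow_angle)


def tracksets_to_csv(tracksets: dict[str, TrackSet], path) -> None:
    pd.concat([ts.to_dataframe() for ts in tracksets.values()],
              ignore_index=True).to_csv(path, index=False)


def tracksets_from_csv(path, flow_angle: float = 0.0) -> dict[str, TrackSet]:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns {sorted(missing)}")
    return {str(g): trackset_from_dataframe(sub, str(g), flow_angle=flow_angle)
            for g, sub in df.groupby("group", sort=True)}
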