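"""Per-cell and ensemble migration statistics.

Implements the standard single-cell migration measures for shear-flow
("flowtaxis") experiments:

* per-frame instantaneous speed, and its per-minute ensemble mean +/- SEM;
* displacement, total path length and their ratio (confinement ratio,
  1 = straight path, 0 = closed loop), over configurable time windows
  (short-term 0-30 min and long-term 0-120 min by default);
* arrest coefficient — the fraction of frames a cell spends below a pause
  threshold, the threshold being one standard deviation below the mean
  static-condition speed;
* net-direction classification and per-step time fractions using the
  +/- pi/8 with/against-flow rule;
* the ensemble root-mean-square displacement

      X_RMS(t) = sqrt( (1/N) * sum_i |x_i(t) - x_i(0)|^2 )

  and the motility coefficient, the slope of X_RMS against sqrt(t) — a
  diffusion-coefficient analogue for cell dispersal, in um/min^(1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

_ANGLE_TOL = 1e-12

PER_CELL_METRICS = ["displacement_um", "path_length_um", "confinement_ratio",
                    "arrest_coefficient", "frac_time_with", "frac_time_against"]


# --------------------------------------------------------------------------
# rules and windows
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """A closed time window [t_start, t_end] in minutes."""

    t_start: float
    t_end: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if not 0 <= self.t_start < self.t_end:
            raise ValueError(f"invalid window [{self.t_start}, {self.t_end}]")

    @staticmethod
    def short_term(t_end: float = 30.0) -> "Window":
        return Window(0.0, t_end, "short_term")

    @staticmethod
    def long_term(t_end: float = 120.0) -> "Window":
        return Window(0.0, t_end, "long_term")


@dataclass(frozen=True)
class ArrestRule:
    """Pause-speed threshold and its provenance (static mean - 1 SD)."""

    threshold: float
    static_mean: float
    static_sd: float

    def __post_init__(self) -> None:
        if not math.isclose(self.threshold, self.static_mean - self.static_sd,
                            rel_tol=0, abs_tol=1e-9):
            raise ValueError("threshold must equal static_mean - static_sd")
        if self.threshold <= 0:
            raise ValueError(
                f"arrest threshold {self.threshold:.4g} um/min is not positive; "
                "the static cohort is too slow/variable — supply an explicit threshold")

    @staticmethod
    def from_mean_sd(mean: float, sd: float) -> "ArrestRule":
        return ArrestRule(mean - sd, mean, sd)


@dataclass(frozen=True)
class DirectionRule:
    """With/against-flow classification: a +/- half_width arc around the flow."""

    flow_angle: float = 0.0
    half_width: float = math.pi / 8

    def __post_init__(self) -> None:
        if not 0 < self.half_width < math.pi / 2:
            raise ValueError("half_width must be in (0, pi/2)")

    def classify(self, vx: float, vy: float) -> str:
        """Classify a vector as ``with | against | neither``.

        The boundary is inclusive; a zero vector is ``neither``.
        """
        if vx == 0 and vy == 0:
            return "neither"
        delta = math.atan2(vy, vx) - self.flow_angle
        delta = (delta + math.pi) % (2 * math.pi) - math.pi
        if abs(delta) <= self.half_width + _ANGLE_TOL:
            return "with"
        if abs(abs(delta) - math.pi) <= self.half_width + _ANGLE_TOL:
            return "against"
        return "neither"


@dataclass
class EnsembleCurve:
    """RMS displacement versus time for one TrackSet."""

    times: np.ndarray
    rms: np.ndarray
    n_cells: int
    group_label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if self.times.shape != self.rms.shape:
            raise ValueError("times and rms must match")
        if self.rms.size and (self.rms[0] != 0 or np.any(self.rms < 0)):
            raise ValueError("rms must be nonnegative with rms[0] = 0")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group_label, "t_min": self.times,
                             "rms_um": self.rms, "n": self.n_cells})


@dataclass(frozen=True)
class MotilityFit:
    """OLS fit of RMS displacement against sqrt(time)."""

    window: Window
    slope: float           # um / min^(1/2)
    intercept: float       # um
    method: str            # "ols" | "ols_through_origin"


# --------------------------------------------------------------------------
# per-track primitives
# --------------------------------------------------------------------------

def frame_speeds(track: Track, dt: float | None = None) -> np.ndarray:
    """Instantaneous speed per frame, um/min: |x(t_k) - x(t_{k-1})| / dt."""
    if track.n_frames < 2:
        raise ValueError("need >= 2 positions for speeds")
    if dt is None:
        dt = track.dt
    elif not np.isclose(dt, track.dt, rtol=0, atol=1e-9):
        raise ValueError("dt does not match the track's time base")
    steps = np.diff(track.xy, axis=0)
    return np.hypot(steps[:, 0], steps[:, 1]) / dt


def _window_slice(track: Track, window: Window) -> slice:
    """Index slice of positions with t in [t_start, t_end]."""
    if (window.t_start < track.t_min[0] - 1e-9
            or window.t_end > track.t_min[-1] + 1e-9):
        raise ValueError(f"window [{window.t_start}, {window.t_end}] min not "
                         f"covered by track spanning [{track.t_min[0]}, {track.t_min[-1]}]")
    inside = (track.t_min >= window.t_start - 1e-9) & (track.t_min <= window.t_end + 1e-9)
    idx = np.flatnonzero(inside)
    if idx.size < 2:
        raise ValueError("window contains fewer than 2 track samples")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def displacement(track: Track, window: Window | None = None) -> float:
    """Net displacement magnitude |x(t_end) - x(t_start)| in um."""
    sl = _window_slice(track, window) if window else slice(None)
    xy = track.xy[sl]
    return float(np.hypot(*(xy[-1] - xy[0])))


def path_length(track: Track, window: Window | None = None) -> float:
    """Total path length (sum of step lengths) in um."""
    sl = _window_slice(track, window) if window else slice(None)
    steps = np.diff(track.xy[sl], axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def confinement_ratio(track: Track, window: Window | None = None) -> float:
    """Displacement / path length; 0 by convention when the path length is 0."""
    p = path_length(track, window)
    return displacement(track, window) / p if p > 0 else 0.0


def arrest_coefficient(track: Track, rule: ArrestRule,
                       window: Window | None = None) -> float:
    """Fraction of window frames with speed strictly below the threshold."""
    sl = _window_slice(track, window) if window else slice(None)
    sub = Track(track.cell_id, track.t_min[sl], track.xy[sl])
    speeds = frame_speeds(sub)
    return float(np.mean(speeds < rule.threshold))


def net_direction_class(track: Track, rule: DirectionRule,
                        window: Window | None = None) -> str:
    """Classify the net displacement vector as with/against/neither."""
    sl = _window_slice(track, window) if window else slice(None)
    xy = track.xy[sl]
    v = xy[-1] - xy[0]
    return rule.classify(float(v[0]), float(v[1]))


def time_direction_fractions(track: Track, rule: DirectionRule,
                             window: Window | None = None) -> tuple[float, float]:
    """Fraction of steps directed with / against the flow (zero steps: neither)."""
    sl = _window_slice(track, window) if window else slice(None)
    steps = np.diff(track.xy[sl], axis=0)
    if len(steps) == 0:
        raise ValueError("need >= 1 step in the window")
    classes = [rule.classify(float(vx), float(vy)) for vx, vy in steps]
    n = len(classes)
    return classes.count("with") / n, classes.count("against") / n


# --------------------------------------------------------------------------
# ensemble statistics
# --------------------------------------------------------------------------

def arrest_rule_from_static(static_trackset: TrackSet, ddof: int = 0) -> ArrestRule:
    """Derive the pause threshold from the static cohort.

    Per-frame speeds are pooled over all static cells and frames; the
    threshold is the pooled mean minus the pooled SD (population SD by
    default; set ``ddof=1`` for the sample convention — indistinguishable on
    realistic pools).
    """
    if static_trackset.n == 0:
        raise ValueError("static group is empty")
    pool = np.concatenate([frame_speeds(tr) for tr in static_trackset.tracks])
    mean, sd = float(pool.mean()), float(pool.std(ddof=ddof))
    if mean - sd <= 0:
        raise ValueError(
            f"derived arrest threshold {mean - sd:.4g} um/min is not positive "
            f"(static mean {mean:.4g}, SD {sd:.4g}); supply an explicit threshold")
    return ArrestRule(mean - sd, mean, sd)


def ensemble_speed_timeseries(trackset: TrackSet) -> pd.DataFrame:
    """Mean +/- SEM speed over cells at each minute.

    SEM = SD(ddof=1)/sqrt(n) over cells; 0 by convention for a single cell.
    Requires complete tracks (equal length), per the TrackSet contract.
    """
    if trackset.n == 0:
        raise ValueError("empty trackset")
    speeds = np.vstack([frame_speeds(tr) for tr in trackset.tracks])  # (n, T-1)
    t = trackset.tracks[0].t_min[1:]
    mean = speeds.mean(axis=0)
    sem = (speeds.std(axis=0, ddof=1) / np.sqrt(trackset.n)
           if trackset.n > 1 else np.zeros_like(mean))
    return pd.DataFrame({"group": trackset.group_label, "t_min": t,
                         "mean_speed_um_min": mean, "sem_um_min": sem,
                         "n": trackset.n})


def rms_displacement_curve(trackset: TrackSet) -> EnsembleCurve:
    """Ensemble RMS displacement X_RMS(t) over all (complete) tracks."""
    if trackset.n == 0:
        raise ValueError("empty trackset")
    lengths = {tr.n_frames for tr in trackset.tracks}
    if len(lengths) != 1:
        raise ValueError("tracks of unequal length; exclude incomplete tracks "
                         "before computing the ensemble curve")
    xy = np.stack([tr.xy for tr in trackset.tracks])      # (n, T, 2)
    disp2 = ((xy - xy[:, :1, :]) ** 2).sum(axis=2)        # squared magnitudes
    rms = np.sqrt(disp2.mean(axis=0))
    return EnsembleCurve(trackset.tracks[0].t_min.copy(), rms, trackset.n,
                         group_label=trackset.group_label)


def motility_coefficient(curve: EnsembleCurve, window: Window | None = None,
                         include_t0: bool = True,
                         through_origin: bool = False) -> MotilityFit:
    """Slope of RMS displacement vs sqrt(time) over a window, um/min^(1/2).

    Ordinary least squares with a free intercept by default (the t = 0 point
    included); ``through_origin=True`` forces the regression line through
    the origin.
    """
    if window is None:
        window = Window(0.0, float(curve.times[-1]), "long_term")
    sel = (curve.times >= window.t_start - 1e-9) & (curve.times <= window.t_end + 1e-9)
    if not include_t0:
        sel &= curve.times > 0
    x = np.sqrt(curve.times[sel])
    y = curve.rms[sel]
    if x.size < 3:
        raise ValueError("need >= 3 time points for the motility fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: all time points identical")
    if through_origin:
        slope = float((x @ y) / (x @ x))
        return MotilityFit(window, slope, 0.0, "ols_through_origin")
    slope, intercept = np.polyfit(x, y, 1)
    return MotilityFit(window, float(slope), float(intercept), "ols")


def summarize_group(trackset: TrackSet, windows, arrest_rule: ArrestRule,
                    direction_rule: DirectionRule | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metric table and group aggregates, per window.

    Returns ``(per_cell, aggregates)``.  ``per_cell`` has one row per cell
    per window with displacement, path length, confinement ratio, arrest
    coefficient, net direction class and with/against time fractions.
    ``aggregates`` carries mean and SEM over cells for each numeric metric
    plus the percentages of cells classed with / against the flow.
    """
    if trackset.n == 0:
        raise ValueError("empty trackset")
    if direction_rule is None:
        direction_rule = DirectionRule(flow_angle=trackset.flow_angle)
    rows = []
    for w in windows:
        for tr in trackset.tracks:
            fw, fa = time_direction_fractions(tr, direction_rule, w)
            rows.append({
                "group": trackset.group_label, "window": w.name, "cell_id": tr.cell_id,
                "displacement_um": displacement(tr, w),
                "path_length_um": path_length(tr, w),
                "confinement_ratio": confinement_ratio(tr, w),
                "arrest_coefficient": arrest_coefficient(tr, arrest_rule, w),
                "net_direction_class": net_direction_class(tr, direction_rule, w),
                "frac_time_with": fw, "frac_time_against": fa,
            })
    per_cell = pd.DataFrame(rows)
    aggs = []
    for w in windows:
        sub = per_cell[per_cell["window"] == w.name]
        n = len(sub)
        row = {"group": trackset.group_label, "window": w.name, "n_cells": n}
        for m in PER_CELL_METRICS:
            vals = sub[m].to_numpy()
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sem"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        row["percent_cells_with"] = 100.0 * (sub["net_direction_class"] == "with").mean()
        row["percent_cells_against"] = 100.0 * (sub["net_direction_class"] == "against").mean()
        aggs.append(row)
    return per_cell, pd.DataFrame(aggs)
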