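"""Figure types for migration data: track plots and ensemble curves."""

from __future__ import annotations

import logging

import matplotlib

matplotlib.use("Agg")  # headless; figures are file artifacts

import matplotlib.pyplot as plt
import numpy as np

from .metrics import EnsembleCurve
from .tracks import TrackSet

log = logging.getLogger(__name__)


def plot_tracks(trackset: TrackSet, style: str = "raw", out_path=None,
                ax=None):
    """Per-cell track figure.

    ``raw`` re-zeroes every track at the origin and draws the full polyline;
    ``compass`` draws one straight segment per cell from the origin to its
    net displacement.  Each cell gets its own colour; the flow direction
    (left to right for flow_angle 0) is annotated.
    """
    if style not in ("raw", "compass"):
        raise ValueError("style must be 'raw' or 'compass'")
    if trackset.n == 0:
        raise ValueError("empty trackset")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab20")
    for i, tr in enumerate(trackset.tracks):
        xy = tr.xy - tr.xy[0]
        color = cmap(i % 20)
        if style == "raw":
            ax.plot(xy[:, 0], xy[:, 1], lw=0.8, color=color)
        else:
            ax.plot([0, xy[-1, 0]], [0, xy[-1, 1]], lw=1.0, color=color)
    lim = max(1.0, float(np.abs([tr.xy - tr.xy[0] for tr in trackset.tracks]).max()) * 1.1)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axhline(0, color="0.85", lw=0.5, zorder=0)
    ax.axvline(0, color="0.85", lw=0.5, zorder=0)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    deg = np.degrees(trackset.flow_angle)
    ax.annotate("flow", xy=(0.95, 0.05), xycoords="axes fraction", ha="right",
                fontsize=8, rotation=deg)
    ax.annotate("", xy=(0.9, 0.08), xytext=(0.7, 0.08), xycoords="axes fraction",
                arrowprops=dict(arrowstyle="->"))
    ax.set_title(f"{trackset.group_label} ({style}, n={trackset.n})")
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_curves(curves, kind: str = "rms", out_path=None, ax=None,
                flow_onset_min: float = 30.0, sem_band: bool = True):
    """Overlaid per-group ensemble curves.

    ``kind="rms"`` plots RMS displacement vs time with a dashed vertical
    marker at ``flow_onset_min`` (the end of the shear-sensitive window);
    ``kind="speed"`` plots per-minute mean speed, optionally with a SEM
    band.  ``curves`` is a mapping group -> EnsembleCurve (rms) or group ->
    speed DataFrame from :func:`ensemble_speed_timeseries`.  Empty entries
    are skipped with a logged warning.
    """
    if kind not in ("rms", "speed"):
        raise ValueError("kind must be 'rms' or 'speed'")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    plotted = 0
    for label, cur in curves.items():
        if kind == "rms":
            if not isinstance(cur, EnsembleCurve) or cur.times.size == 0:
                log.warning("skipping empty/invalid curve for group %r", label)
                continue
            ax.plot(cur.times, cur.rms, label=str(label))
        else:
            if cur is None or len(cur) == 0:
                log.warning("skipping empty speed series for group %r", label)
                continue
            ax.plot(cur["t_min"], cur["mean_speed_um_min"], label=str(label))
            if sem_band:
                lo = cur["mean_speed_um_min"] - cur["sem_um_min"]
                hi = cur["mean_speed_um_min"] + cur["sem_um_min"]
                ax.fill_between(cur["t_min"], lo, hi, alpha=0.2)
        plotted += 1
    if plotted == 0:
        raise ValueError("no plottable curves")
    if kind == "rms":
        ax.axvline(flow_onset_min, ls="--", color="0.4", lw=1.0)
        ax.set_ylabel("RMS displacement (um)")
    else:
        ax.set_ylabel("mean speed (um/min)")
    ax.set_xlabel("time (min)")
    ax.legend(fontsize=8)
    if out_path is not None:
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
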