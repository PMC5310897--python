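"""Synthetic cohorts of migrating cells.

The generator is a two-state (motile/paused) biased persistent random walk
with an exponentially decaying speed transient.  It is the minimal model able
to reproduce the phenomena the analysis layer quantifies: shear-ordered
initial speed, a transient sensitivity window, group differences in pausing,
and recruitment of net migration toward the flow direction (+x).

Per step (frame interval ``dt``), for a cell in the motile state the heading
theta receives wrapped-normal noise of SD ``persistence_sigma`` plus a
deterministic pull ``bias_kappa * sin(-theta)`` toward the flow axis, and the
step speed is drawn as ``max(0, Normal(mu(t), speed_sd))`` with

    mu(t) = base_speed * (1 + transient_amp * exp(-t / transient_tau)).

In the paused state the cell jitters by ``pause_speed * dt`` in a uniformly
random direction.  State switches are a Markov chain with per-frame
probabilities ``p_pause`` (motile -> paused) and ``p_resume``; the initial
state is drawn from the chain's stationary distribution so windowed pause
statistics are unbiased.

Shear stress (dyne/cm^2) is metadata only: it selects a parameter preset and
never enters the equations of motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .tracks import Track, TrackSet

GROUP_ORDER = ("static", "FF2", "FF15", "FF25")


@dataclass
class SimParams:
    """Parameters of the two-state biased persistent random walk.

    Speeds are in um/min, times in minutes, angles in radians.
    """

    n_cells: int = 30
    n_frames: int = 121          # covers 0-120 min at dt = 1
    dt: float = 1.0
    base_speed: float = 0.3      # motile-state mean step speed, um/min
    speed_sd: float = 0.1
    transient_amp: float = 0.0   # initial speed boost factor (dimensionless)
    transient_tau: float = 10.0  # decay constant of the boost, min
    bias_kappa: float = 0.0      # pull strength toward the flow axis
    persistence_sigma: float = 0.8  # heading noise SD per step, rad
    p_pause: float = 0.0         # P(motile -> paused) per frame
    p_resume: float = 1.0        # P(paused -> motile) per frame
    pause_speed: float = 0.0     # jitter magnitude while paused, um/min
    group_label: str = "static"

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "group_label":
                continue
            if not np.isfinite(v):
                raise ValueError(f"SimParams.{f.name} must be finite, got {v!r}")
        if self.n_frames < 2:
            raise ValueError("SimParams.n_frames must be >= 2")
        if self.n_cells < 1:
            raise ValueError("SimParams.n_cells must be >= 1")
        for name in ("dt", "transient_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimParams.{name} must be positive")
        for name in ("base_speed", "speed_sd", "transient_amp", "bias_kappa",
                     "persistence_sigma", "pause_speed"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be >= 0")
        for name in ("p_pause", "p_resume"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"SimParams.{name} must be in [0, 1], got {p}")

    def stationary_paused_fraction(self) -> float:
        """Stationary probability of the paused state."""
        s = self.p_pause + self.p_resume
        return self.p_pause / s if s > 0 else 0.0

    def mean_motile_speed(self, t: float) -> float:
        """Mean of the (untruncated) motile speed draw at time ``t``."""
        return self.base_speed * (1.0 + self.transient_amp * math.exp(-t / self.transient_tau))


def simulate_positions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Simulate all cells of one condition at once.

    Returns an ``(n_cells, n_frames, 2)`` array of positions in um, every
    cell starting at the origin.  Vectorised over cells; the per-frame loop
    is sequential because heading and state are Markov.  Random draws are
    consumed for every cell at every step regardless of state, so the stream
    layout (hence reproducibility) does not depend on the realised states.
    """
    params.validate()
    n, T = params.n_cells, params.n_frames
    pos = np.zeros((n, T, 2))
    theta = rng.uniform(-np.pi, np.pi, n)
    paused = rng.random(n) < params.stationary_paused_fraction()
    for k in range(T - 1):
        t = k * params.dt
        dtheta = rng.normal(0.0, params.persistence_sigma, n)
        speed = np.maximum(0.0, rng.normal(params.mean_motile_speed(t), params.speed_sd, n))
        phi = rng.uniform(-np.pi, np.pi, n)
        u = rng.random(n)

        theta = np.where(paused, theta,
                         theta + params.bias_kappa * np.sin(-theta) + dtheta)
        step_len = np.where(paused, params.pause_speed, speed) * params.dt
        ang = np.where(paused, phi, theta)
        pos[:, k + 1, 0] = pos[:, k, 0] + step_len * np.cos(ang)
        pos[:, k + 1, 1] = pos[:, k, 1] + step_len * np.sin(ang)

        paused = np.where(paused, u >= params.p_resume, u < params.p_pause)
    return pos


def simulate_track(params: SimParams, rng: np.random.Generator) -> Track:
    """Simulate a single cell (``params.n_cells`` is ignored)."""
    single = replace(params, n_cells=1)
    pos = simulate_positions(single, rng)[0]
    t = np.arange(params.n_frames) * params.dt
    return Track(cell_id=0, t_min=t, xy=pos)


def simulate_trackset(params: SimParams, rng: np.random.Generator,
                      flow_angle: float = 0.0) -> TrackSet:
    pos = simulate_positions(params, rng)
    t = np.arange(params.n_frames) * params.dt
    tracks = [Track(cell_id=i, t_min=t, xy=pos[i]) for i in range(params.n_cells)]
    return TrackSet(params.group_label, tracks, dt=params.dt, flow_angle=flow_angle)


# --------------------------------------------------------------------------
# presets
#
# The vector-control cohort emulates osteoblasts under steady flow at 0 / 2 /
# 15 / 25 dyne/cm^2: a shared motile base speed with a shear-ordered initial
# transient (amplitudes set once from pause-mixture arithmetic so pooled
# 1-min ensemble speeds land near 0.20 / 0.42 / 0.57 / 0.81 um/min and
# short-term arrest decreases with shear), shear-ordered pause occupancy,
# and a shear-ordered heading bias toward +x.
# The ROCK-knockdown preset raises base speed and persistence, slows the
# transient decay (a sustained shear-sensitive window) and nearly removes
# pausing.  The "null" preset gives four identically parameterised groups as
# a negative control for the statistics layer.
# --------------------------------------------------------------------------

_CONTROL_COMMON = dict(n_cells=30, n_frames=121, dt=1.0, base_speed=0.22,
                       speed_sd=0.10, transient_tau=10.0, pause_speed=0.05,
                       persistence_sigma=0.8)

_PRESETS: dict[str, dict[str, dict]] = {
    "paper_osteoblast": {
        "static": dict(_CONTROL_COMMON, transient_amp=0.0, bias_kappa=0.0,
                       p_pause=0.090, p_resume=0.410, group_label="static"),
        "FF2": dict(_CONTROL_COMMON, transient_amp=1.1, bias_kappa=0.15,
                    p_pause=0.080, p_resume=0.420, group_label="FF2"),
        "FF15": dict(_CONTROL_COMMON, transient_amp=1.9, bias_kappa=0.30,
                     p_pause=0.045, p_resume=0.455, group_label="FF15"),
        "FF25": dict(_CONTROL_COMMON, transient_amp=3.2, bias_kappa=0.45,
                     p_pause=0.025, p_resume=0.475, group_label="FF25"),
    },
    "paper_rock_sh": {
        # vector control at the two conditions the knockdown was compared at
        "static-control": dict(_CONTROL_COMMON, transient_amp=0.0, bias_kappa=0.0,
                               p_pause=0.090, p_resume=0.410,
                               group_label="static-control"),
        "FF25-control": dict(_CONTROL_COMMON, transient_amp=3.2, bias_kappa=0.45,
                             p_pause=0.025, p_resume=0.475,
                             group_label="FF25-control"),
        # knockdown: faster, less pausing; static knockdown wanders (high
        # heading noise, no bias) while sheared knockdown migrates
        # persistently with the flow and keeps its transient far longer
        "static-ROCKsh": dict(_CONTROL_COMMON, base_speed=0.30,
                              transient_amp=0.0, bias_kappa=0.0,
                              persistence_sigma=1.8, p_pause=0.02, p_resume=0.48,
                              group_label="static-ROCKsh"),
        "FF25-ROCKsh": dict(_CONTROL_COMMON, base_speed=0.30,
                            transient_amp=2.0, transient_tau=40.0, bias_kappa=0.7,
                            persistence_sigma=0.45, p_pause=0.02, p_resume=0.48,
                            group_label="FF25-ROCKsh"),
    },
    "null": {
        g: dict(_CONTROL_COMMON, transient_amp=0.0, bias_kappa=0.0,
                p_pause=0.090, p_resume=0.410, group_label=g)
        for g in GROUP_ORDER
    },
}


def preset_params(preset_name: str) -> dict[str, SimParams]:
    """The documented parameters of a named preset, one SimParams per group."""
    try:
        spec = _PRESETS[preset_name]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(_PRESETS)}") from None
    return {g: SimParams(**kw) for g, kw in spec.items()}


def simulate_cohort(preset_name: str, overrides: dict | None = None,
                    seed: int = 0, flow_angle: float = 0.0) -> dict[str, TrackSet]:
    """Simulate one TrackSet per group of a named preset.

    ``overrides`` maps SimParams field names to values applied to every
    group, or group labels to such mappings for per-group overrides.
    Reproducible: each group gets an independent child stream spawned from
    ``seed``, so the result is byte-identical across runs and platforms.
    """
    groups = preset_params(preset_name)
    overrides = overrides or {}
    per_group = {g: {} for g in groups}
    for key, val in overrides.items():
        if key in groups:
            per_group[key].update(val)
        else:
            for g in per_group:
                per_group[g][key] = val
    streams = np.random.SeedSequence(seed).spawn(len(groups))
    out = {}
    for (g, params), ss in zip(groups.items(), streams):
        params = replace(params, **per_group[g])
        out[g] = simulate_trackset(params, np.random.default_rng(ss),
                                   flow_angle=flow_angle)
    return out
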