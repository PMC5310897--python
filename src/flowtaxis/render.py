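"""Render simulated cohorts as phase-contrast-like image stacks.

Each cell is drawn as a dark disk with a bright rim (the phase halo) on a
mid-grey background scattered with small static debris marks, as on a real
slide; the whole scene — cells and debris — is shifted by a per-frame drift
schedule, and per-frame Gaussian noise is added.  The debris gives the
drift-correction template region genuine structure to match against, while
staying below the segmentation area cutoff.  The exact per-frame centroids
and the drift schedule are returned alongside the stack so the image
pipeline can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .imaging import ImageStack
from .tracks import TrackSet

TRUTH_COLUMNS = ["group", "cell_id", "frame", "t_min", "x_um", "y_um", "in_frame"]

_BACKGROUND = 0.55
_INTERIOR = 0.15
_HALO = 0.95


@dataclass
class RenderParams:
    """Rendering geometry and noise model."""

    image_shape: tuple[int, int] = (256, 256)  # (rows, cols) px
    pixel_size: float = 1.0                    # um per px
    cell_radius: int = 6                       # px
    halo: bool = True                          # bright phase-contrast rim
    noise_sd: float = 0.01                     # intensity units (range ~1)
    drift_schedule: np.ndarray | None = None   # (T, 2) int (dy, dx), else no drift
    debris_count: int = 40                     # static sub-cellular marks
    debris_radius: int = 2                     # px; keep area < min_area

    def __post_init__(self) -> None:
        if self.cell_radius < 2:
            raise ValueError("cell_radius must be >= 2 px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.debris_count < 0 or self.debris_radius < 1:
            raise ValueError("debris_count must be >= 0, debris_radius >= 1")
        if self.drift_schedule is not None:
            self.drift_schedule = np.asarray(self.drift_schedule, dtype=int)
            if self.drift_schedule.ndim != 2 or self.drift_schedule.shape[1] != 2:
                raise ValueError("drift_schedule must be (T, 2)")


def _grid_origins(n: int, shape: tuple[int, int], margin: float,
                  spacing: float) -> np.ndarray:
    """Deterministic well-separated start positions, px (x, y)."""
    H, W = shape
    usable_w, usable_h = W - 2 * margin, H - 2 * margin
    if usable_w <= 0 or usable_h <= 0:
        raise ValueError("image too small for the requested margin")
    cols = max(1, int(usable_w // spacing) + 1)
    rows = max(1, int(usable_h // spacing) + 1)
    if cols * rows < n:
        raise ValueError(f"cannot place {n} cells with spacing {spacing:.0f} px "
                         f"in a {H}x{W} image; enlarge the image")
    origins = []
    for i in range(n):
        r, c = divmod(i, cols)
        origins.append((margin + c * spacing, margin + r * spacing))
    return np.asarray(origins, dtype=float)


def _debris_sites(rp: RenderParams, origins: np.ndarray, keepout: float,
                  max_drift: int, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Static (y, x, intensity) marks: a coarse deterministic grid for
    coverage (so any reasonable template box has structure) plus random
    extras, all clear of cell paths and of the drifting border."""
    if rp.debris_count == 0:
        return []
    H, W = rp.image_shape
    border = rp.debris_radius + max_drift + 1
    # keep marks apart so their local-entropy footprints stay below any
    # sensible segmentation area cutoff instead of chaining together
    min_sep = 18.0
    sites: list[tuple[float, float, float]] = []

    def clear(y: float, x: float) -> bool:
        if not (border <= y < H - border and border <= x < W - border):
            return False
        if any(np.hypot(sy - y, sx - x) < min_sep for sy, sx, _ in sites):
            return False
        return (np.hypot(origins[:, 0] - x, origins[:, 1] - y) > keepout).all()

    step = max(24, min(H, W) // 6)
    shades = (0.15, 0.9)
    k = 0
    for y in range(border + 4, H - border, step):
        for x in range(border + 4, W - border, step):
            if clear(y, x):
                sites.append((float(y), float(x), shades[k % 2]))
                k += 1
    tries = 0
    while len(sites) < rp.debris_count and tries < 50 * rp.debris_count:
        y, x = rng.uniform(0, H), rng.uniform(0, W)
        tries += 1
        if clear(y, x):
            sites.append((y, x, float(rng.uniform(0.1, 0.35))
                          if rng.random() < 0.5 else float(rng.uniform(0.75, 0.95))))
    return sites


def render_stack(trackset: TrackSet, rp: RenderParams, rng: np.random.Generator,
                 origins: np.ndarray | None = None,
                 ) -> tuple[ImageStack, pd.DataFrame, np.ndarray]:
    """Render a TrackSet as an image stack with ground truth.

    Returns ``(stack, truth, drift_schedule)`` where ``truth`` holds the
    exact drift-free centroid of every cell at every frame (um) and an
    ``in_frame`` flag that is False once any part of the blob leaves the
    frame (such cells exercise the exclusion rules downstream; they are
    drawn clipped, never raised as errors).

    Start positions default to a deterministic grid with spacing wide enough
    that well-separated simulated cohorts stay well separated when rendered.
    """
    T = max(tr.n_frames for tr in trackset.tracks)
    H, W = rp.image_shape
    drift = rp.drift_schedule
    if drift is None:
        drift = np.zeros((T, 2), dtype=int)
    if drift.shape[0] != T:
        raise ValueError("drift_schedule length must equal the track length")
    max_drift = int(np.abs(drift).max()) if drift.size else 0

    # maximum blob excursion in px, to size the placement grid
    reach = max(float(np.abs(tr.xy - tr.xy[0]).max()) for tr in trackset.tracks)
    reach_px = reach / rp.pixel_size
    rim = rp.cell_radius + 2
    if origins is None:
        margin = rim + max_drift + reach_px + 2
        spacing = 2 * reach_px + 4 * rp.cell_radius + 8
        origins = _grid_origins(trackset.n, rp.image_shape, margin, spacing)
    else:
        origins = np.asarray(origins, dtype=float)

    # 10 px extra so debris local-entropy footprints never attach to a cell
    keepout = rim + reach_px + rp.debris_radius + 10
    debris = _debris_sites(rp, origins, keepout, max_drift, rng)

    frames = np.empty((T, H, W))
    truth_rows = []
    for f in range(T):
        dy, dx = drift[f]
        img = np.full((H, W), _BACKGROUND)
        for (by, bx, shade) in debris:
            rr, cc = draw_disk((by + dy, bx + dx), rp.debris_radius, shape=(H, W))
            img[rr, cc] = shade
        for i, tr in enumerate(trackset.tracks):
            disp = (tr.xy[f] - tr.xy[0]) / rp.pixel_size
            cx, cy = origins[i, 0] + disp[0], origins[i, 1] + disp[1]
            in_frame = (rim <= cx <= W - 1 - rim) and (rim <= cy <= H - 1 - rim)
            # drawn at the drifted position; truth records drift-free um
            ry, rx = cy + dy, cx + dx
            if rp.halo:
                rr, cc = draw_disk((ry, rx), rp.cell_radius + 2, shape=(H, W))
                img[rr, cc] = _HALO
            rr, cc = draw_disk((ry, rx), rp.cell_radius, shape=(H, W))
            img[rr, cc] = _INTERIOR
            truth_rows.append((trackset.group_label, tr.cell_id, f, tr.t_min[f],
                               cx * rp.pixel_size, cy * rp.pixel_size, in_frame))
        if rp.noise_sd > 0:
            img = img + rng.normal(0.0, rp.noise_sd, (H, W))
        frames[f] = np.clip(img, 0.0, 1.0)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    stack = ImageStack(frames, pixel_size=rp.pixel_size, dt=trackset.dt)
    return stack, truth, drift
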