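"""Image pipeline: drift correction and phase-contrast segmentation.

Turns a raw time-lapse stack into per-frame cell centroids in three steps:

1. stage/device drift estimation by normalised cross-correlation of a fixed
   cell-free template region against every frame (integer-pixel shifts);
2. translation of every frame by the negated shift (nearest-edge padding);
3. per-frame segmentation by the union of two binary masks — Otsu-thresholded
   local image entropy, and Otsu-thresholded Sobel gradient magnitude —
   followed by hole filling, a radius-1 opening and small-object removal.

Coordinates are row-major: x = column (the flow direction), y = row, origin
at the top-left of frame 0; centroids are reported in micrometres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import match_template
from skimage.filters import sobel, threshold_otsu
from skimage.filters.rank import entropy as rank_entropy
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk

log = logging.getLogger(__name__)

DETECTION_COLUMNS = ["frame", "x_um", "y_um", "area_px", "touches_border", "merged"]


@dataclass
class ImageStack:
    """Time-ordered grayscale frames with physical metadata."""

    frames: np.ndarray   # (T, H, W)
    pixel_size: float    # um per pixel
    dt: float            # minutes per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T, H, W) with T >= 2")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DriftEstimate:
    """Per-frame (dy, dx) integer shifts relative to frame 0."""

    shifts: np.ndarray  # (T, 2) int

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (T, 2)")
        if np.any(self.shifts[0] != 0):
            raise ValueError("shifts[0] must be (0, 0)")


@dataclass
class Detection:
    """One segmented connected component in one frame."""

    frame: int
    x_um: float
    y_um: float
    area_px: int
    touches_border: bool
    merged: bool


def estimate_drift(stack: ImageStack, template_box: tuple[int, int, int, int],
                   search_radius: int = 20) -> DriftEstimate:
    """Estimate per-frame drift from a fixed cell-free template region.

    ``template_box`` is ``(y0, x0, h, w)`` in frame-0 pixel coordinates.  For
    every frame the template is matched by normalised cross-correlation
    within ``+/- search_radius`` pixels of its frame-0 position; the
    integer-pixel argmax is the frame's shift.  Correlation ties are broken
    by smallest shift magnitude, then lexicographically by (dy, dx).

    Raises ``ValueError`` for a zero-variance (flat) template, which carries
    no registration signal — choose a textured region instead.
    """
    y0, x0, h, w = template_box
    H, W = stack.shape
    if not (0 <= y0 and 0 <= x0 and y0 + h <= H and x0 + w <= W and h > 0 and w > 0):
        raise ValueError(f"template_box {template_box} outside {H}x{W} frames")
    template = np.asarray(stack.frames[0, y0:y0 + h, x0:x0 + w], dtype=float)
    if np.ptp(template) == 0:
        raise ValueError("flat (zero-variance) template; choose a textured, "
                         "cell-free region with intensity structure")
    s = int(search_radius)
    top, left = max(0, y0 - s), max(0, x0 - s)
    bottom, right = min(H, y0 + h + s), min(W, x0 + w + s)
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    for f in range(1, stack.n_frames):
        region = np.asarray(stack.frames[f, top:bottom, left:right], dtype=float)
        score = match_template(region, template)
        best = score.max()
        cand = np.argwhere(score >= best - 1e-9)
        dyx = cand + [top - y0, left - x0]
        order = np.lexsort((dyx[:, 1], dyx[:, 0], (dyx ** 2).sum(axis=1)))
        shifts[f] = dyx[order[0]]
    return DriftEstimate(shifts)


def apply_drift(stack: ImageStack, drift: DriftEstimate) -> ImageStack:
    """Translate each frame by the negated shift, nearest-edge padding."""
    if drift.shifts.shape[0] != stack.n_frames:
        raise ValueError("drift length does not match stack")
    out = np.empty_like(stack.frames, dtype=float)
    for f in range(stack.n_frames):
        dy, dx = drift.shifts[f]
        out[f] = ndi.shift(np.asarray(stack.frames[f], dtype=float),
                           (-dy, -dx), order=0, mode="nearest")
    return ImageStack(out, pixel_size=stack.pixel_size, dt=stack.dt)


def _to_uint8(frame: np.ndarray) -> np.ndarray:
    # frames already in [0, 1] keep a fixed scale so noise is not stretched
    lo, hi = float(frame.min()), float(frame.max())
    if 0.0 <= lo and hi <= 1.0:
        return np.round(255 * frame).astype(np.uint8)
    if hi == lo:
        return np.zeros(frame.shape, dtype=np.uint8)
    return (255 * (frame - lo) / (hi - lo)).astype(np.uint8)


def _otsu_mask(image: np.ndarray, max_foreground_frac: float) -> np.ndarray:
    """Otsu-threshold ``image``, rejecting a degenerate split.

    Cells are sparse bright-feature foreground; when Otsu claims more than
    ``max_foreground_frac`` of the pixels it has split a near-uniform
    background (e.g. pure noise) rather than found objects, and the mask is
    returned empty.
    """
    if np.ptp(image) == 0:
        return np.zeros(image.shape, dtype=bool)
    mask = image > threshold_otsu(image)
    if mask.mean() > max_foreground_frac:
        return np.zeros(image.shape, dtype=bool)
    return mask


def segment_frame(frame: np.ndarray, entropy_radius: int = 5, min_area: int = 30,
                  merge_area_factor: float = 1.8, combine: str = "or",
                  pixel_size: float = 1.0, frame_index: int = 0,
                  max_foreground_frac: float = 0.35,
                  ) -> tuple[np.ndarray, list[Detection]]:
    """Segment one frame into labelled cells.

    The cell mask is the union (configurable: ``combine="and"``) of an
    entropy mask (Otsu threshold on the local entropy within a disk of
    ``entropy_radius``) and an edge mask (Otsu threshold on the Sobel
    gradient magnitude).  Either mask is discarded if its foreground
    fraction exceeds ``max_foreground_frac`` (see :func:`_otsu_mask`).
    Holes are filled, a radius-1 opening removes speckle, and components
    smaller than ``min_area`` px^2 are dropped.

    Each remaining 8-connected component becomes a :class:`Detection` whose
    centroid is the unweighted mean of member pixel coordinates converted to
    um.  ``merged`` flags components larger than ``merge_area_factor`` times
    the frame's median component area (plausibly touching cells);
    ``touches_border`` flags components reaching the image edge.

    A constant frame yields zero detections (not an error).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if np.ptp(frame) == 0:
        return np.zeros(frame.shape, dtype=int), []
    if combine not in ("or", "and"):
        raise ValueError("combine must be 'or' or 'and'")

    ent = rank_entropy(_to_uint8(frame), disk(entropy_radius))
    entropy_mask = _otsu_mask(ent, max_foreground_frac)
    edge_mask = _otsu_mask(sobel(frame), max_foreground_frac)
    mask = entropy_mask | edge_mask if combine == "or" else entropy_mask & edge_mask

    mask = ndi.binary_fill_holes(mask)
    mask = ndi.binary_opening(mask, structure=disk(1))
    labels = cc_label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area)
    if small.size:
        mask &= ~np.isin(labels, small[small > 0])
        labels = cc_label(mask, connectivity=2)

    props = regionprops(labels)
    if not props:
        return labels, []
    median_area = float(np.median([p.area for p in props]))
    H, W = frame.shape
    detections = []
    for p in props:
        cy, cx = p.centroid  # (row, col) unweighted pixel mean
        minr, minc, maxr, maxc = p.bbox
        detections.append(Detection(
            frame=frame_index,
            x_um=cx * pixel_size,
            y_um=cy * pixel_size,
            area_px=int(p.area),
            touches_border=bool(minr == 0 or minc == 0 or maxr == H or maxc == W),
            merged=bool(p.area > merge_area_factor * median_area),
        ))
    return labels, detections


def segment_stack(stack: ImageStack, entropy_radius: int = 5, min_area: int = 30,
                  merge_area_factor: float = 1.8, combine: str = "or",
                  max_foreground_frac: float = 0.35, return_labels: bool = False):
    """Segment every frame of a (drift-corrected) stack.

    Returns a detections DataFrame (columns ``frame, x_um, y_um, area_px,
    touches_border, merged``), plus the label stack when ``return_labels``.
    Empty frames are logged, never raised.
    """
    all_dets: list[Detection] = []
    label_frames = []
    for f in range(stack.n_frames):
        labels, dets = segment_frame(
            stack.frames[f], entropy_radius=entropy_radius, min_area=min_area,
            merge_area_factor=merge_area_factor, combine=combine,
            max_foreground_frac=max_foreground_frac,
            pixel_size=stack.pixel_size, frame_index=f)
        if not dets:
            log.warning("frame %d: no detections", f)
        log.debug("frame %d: %d detections", f, len(dets))
        all_dets.extend(dets)
        if return_labels:
            label_frames.append(labels)
    df = pd.DataFrame([d.__dict__ for d in all_dets], columns=DETECTION_COLUMNS)
    if return_labels:
        return df, np.stack(label_frames)
    return df


def read_stack(path, pixel_size: float, dt: float) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack."""
    import tifffile

    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, pixel_size=pixel_size, dt=dt)


def write_stack(path, stack_or_frames) -> None:
    """Write frames (or an ImageStack) as a multi-page TIFF."""
    import tifffile

    frames = getattr(stack_or_frames, "frames", stack_or_frames)
    frames = np.asarray(frames)
    if frames.dtype.kind == "f":
        frames = np.clip(frames, 0, 1)
        frames = (frames * 65535).astype(np.uint16)
    tifffile.imwrite(path, frames)
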