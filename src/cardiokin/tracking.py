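"""Grid-based spot tracking by normalized cross-correlation.

Thirty markers are placed on an orthogonal grid over the first frame and each
is followed through the stack by correlating a static frame-0 template
against a search window centered on the marker's previous position. The
integer-pixel correlation peak is refined to sub-pixel precision by 3-point
parabolic interpolation independently in x and y.

The template is deliberately *not* updated from frame to frame: recordings
are short (20 s) under constant illumination, and a static template cannot
accumulate drift.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .synthgen import ImageStack
from .trajectories import (
    MarkerTrajectory,
    TimeBase,
    TrajectorySet,
    read_trajectories,
    write_trajectories,
)

__all__ = [
    "MarkerGrid",
    "TrackParams",
    "place_marker_grid",
    "track_spot",
    "track_all",
    "quality_report",
    "read_trajectories",
    "write_trajectories",
    "read_stack",
]


@dataclass(frozen=True)
class MarkerGrid:
    """Uniform lattice of marker seed positions on the first frame."""

    positions: np.ndarray  # (M, 2) of (x, y)
    rows: int
    cols: int
    margin: float

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class TrackParams:
    template_radius: int = 8     # half-size of the frame-0 template [px]
    search_radius: int = 10      # max displacement searched per frame [px]
    corr_floor: float = 0.2      # below this the frame counts as lost


def place_marker_grid(width: int, height: int, rows: int = 5, cols: int = 6,
                      margin: float = 40.0) -> MarkerGrid:
    """Nodes of a uniform ``rows x cols`` lattice spanning
    ``[margin, width - margin] x [margin, height - margin]``.

    A single row (column) sits at the frame mid-height (mid-width).
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if 2 * margin >= width or 2 * margin >= height:
        raise ValueError(
            f"grid does not fit: need frame larger than "
            f"{2 * margin:.0f} x {2 * margin:.0f} px for margin {margin}")
    xs = np.linspace(margin, width - margin, cols) if cols > 1 \
        else np.array([width / 2.0])
    ys = np.linspace(margin, height - margin, rows) if rows > 1 \
        else np.array([height / 2.0])
    gx, gy = np.meshgrid(xs, ys)
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    return MarkerGrid(positions, rows, cols, margin)


def _parabolic_offset(ym1: float, y0: float, yp1: float) -> float:
    """Sub-sample offset of the vertex of a parabola through 3 points."""
    denom = ym1 - 2 * y0 + yp1
    if denom >= 0:  # not a maximum; fall back to the integer peak
        return 0.0
    off = 0.5 * (ym1 - yp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_spot(stack: ImageStack, init: tuple[float, float],
               params: TrackParams = TrackParams(),
               marker_id: int = 0) -> MarkerTrajectory:
    """Track one spot through the stack from its frame-0 position.

    Frames whose correlation peak falls below ``corr_floor`` are marked lost
    and hold the previous position (keeping the series uniformly sampled for
    differentiation).

    The template is cut on the integer pixel grid, so the correlation can
    only measure motion relative to frame 0; reported positions are anchored
    at the caller's (sub-pixel) ``init`` plus that tracked motion. Any error
    in ``init`` therefore carries through as a constant offset, exactly as
    with manually placed markers.
    """
    frames = stack.frames.astype(float)
    n, h, w = frames.shape
    if n < 2:
        raise ValueError("at least 2 frames required")
    r, sr = params.template_radius, params.search_radius
    x0, y0 = int(round(init[0])), int(round(init[1]))
    if not (r <= x0 < w - r and r <= y0 < h - r):
        raise ValueError(
            f"template window around ({init[0]:.0f}, {init[1]:.0f}) does not "
            f"fit inside the {w}x{h} frame")
    template = frames[0, y0 - r:y0 + r + 1, x0 - r:x0 + r + 1]

    xs = np.empty(n)
    ys = np.empty(n)
    quality = np.empty(n)
    lost = np.zeros(n, dtype=bool)
    px, py = float(x0), float(y0)
    for f in range(n):
        cx, cy = int(round(px)), int(round(py))
        half = sr + r
        yl, yh = max(cy - half, 0), min(cy + half + 1, h)
        xl, xh = max(cx - half, 0), min(cx + half + 1, w)
        window = frames[f, yl:yh, xl:xh]
        if window.shape[0] < 2 * r + 1 or window.shape[1] < 2 * r + 1:
            lost[f] = True
            quality[f] = np.nan
            xs[f], ys[f] = px, py
            continue
        corr = match_template(window, template)
        iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
        peak = corr[iy, ix]
        quality[f] = peak
        if peak < params.corr_floor:
            lost[f] = True
            xs[f], ys[f] = px, py
            continue
        dx = _parabolic_offset(*corr[iy, ix - 1:ix + 2]) \
            if 0 < ix < corr.shape[1] - 1 else 0.0
        dy = _parabolic_offset(*corr[iy - 1:iy + 2, ix]) \
            if 0 < iy < corr.shape[0] - 1 else 0.0
        px = xl + ix + r + dx
        py = yl + iy + r + dy
        xs[f], ys[f] = px, py
    if lost.mean() > 0.2:
        warnings.warn(
            f"marker {marker_id}: {int(lost.sum())}/{n} frames lost; "
            "trajectory flagged invalid", stacklevel=2)
    # re-anchor from the integer template grid to the sub-pixel init
    xs += init[0] - x0
    ys += init[1] - y0
    return MarkerTrajectory(marker_id, xs, ys, quality=quality, lost=lost)


def track_all(stack: ImageStack, grid: MarkerGrid,
              params: TrackParams = TrackParams()) -> TrajectorySet:
    """Track every grid node; fails if more than half the markers go invalid."""
    trajectories = [
        track_spot(stack, tuple(pos), params, marker_id=m)
        for m, pos in enumerate(grid.positions)
    ]
    n_invalid = sum(not tr.valid for tr in trajectories)
    if n_invalid > 0.5 * len(trajectories):
        raise RuntimeError(
            f"{n_invalid}/{len(trajectories)} markers lost more than 20% of "
            "frames; tracking failed")
    return TrajectorySet(stack.timebase, trajectories)


def quality_report(ts: TrajectorySet) -> dict:
    """Per-marker tracking quality (mean correlation, lost-frame count)."""
    report = {
        "n_markers": ts.n_markers,
        "n_frames": ts.timebase.n_frames,
        "markers": [],
    }
    for tr in ts.trajectories:
        q = tr.quality
        report["markers"].append(
            {
                "marker_id": tr.marker_id,
                "mean_correlation": float(np.nanmean(q)) if q is not None else None,
                "lost_frames": tr.n_lost,
                "valid": tr.valid,
            }
        )
    return report


def write_quality_report(ts: TrajectorySet, path) -> None:
    with open(path, "w") as fh:
        json.dump(quality_report(ts), fh, indent=2)


def read_stack(path, fs: float) -> ImageStack:
    """Load a multi-page TIFF (or AVI, via imageio) as a grayscale stack."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        frames = iio.imread(path)
        if frames.ndim == 4:  # RGB video -> luminance
            frames = frames.astype(float) @ np.array([0.299, 0.587, 0.114])
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames, TimeBase(fs, frames.shape[0]))
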