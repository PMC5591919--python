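"""Core containers for marker trajectories and their CSV round trip.

Coordinate convention throughout the package: origin at the top-left pixel
center, ``x`` increases rightward (columns), ``y`` downward (rows), positions
are continuous (sub-pixel) pixel coordinates. Time stamps are uniform,
``t_i = i / fs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ARMS = ("CTRL", "ISO", "EMF", "ISO+EMF")

TRAJECTORY_COLUMNS = ["marker_id", "frame", "t_s", "x_px", "y_px"]


class TrajectoryParseError(ValueError):
    """Raised when a trajectory table violates the on-disk schema."""


@dataclass(frozen=True)
class TimeBase:
    """Uniform sampling grid of a video: ``t_i = i / fs``."""

    fs: float
    n_frames: int

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.n_frames < 2:
            raise ValueError(f"need at least 2 frames, got {self.n_frames}")

    @property
    def duration(self) -> float:
        return self.n_frames / self.fs

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


@dataclass
class MarkerTrajectory:
    """Continuous (x, y) pixel path of one marker through a video.

    ``quality`` holds the per-frame template-correlation score for tracked
    trajectories (NaN for synthetic ones); ``lost`` marks frames where the
    tracker fell below the correlation floor and held the last position.
    """

    marker_id: int
    x: np.ndarray
    y: np.ndarray
    quality: np.ndarray | None = None
    lost: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n_frames(self) -> int:
        return self.x.size

    @property
    def n_lost(self) -> int:
        return 0 if self.lost is None else int(np.sum(self.lost))

    @property
    def valid(self) -> bool:
        """A trajectory is invalid once more than 20% of frames are lost."""
        return self.n_lost <= 0.2 * self.n_frames


@dataclass
class TrajectorySet:
    """All marker trajectories of one 20 s video of one syncytium."""

    timebase: TimeBase
    trajectories: list[MarkerTrajectory]
    syncytium_id: int = 0
    condition: str = "CTRL"
    minute: int = 0

    def __post_init__(self) -> None:
        for tr in self.trajectories:
            if tr.n_frames != self.timebase.n_frames:
                raise ValueError(
                    f"marker {tr.marker_id}: {tr.n_frames} frames, "
                    f"timebase has {self.timebase.n_frames}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.trajectories)

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack trajectories into (M, T) arrays of x and y coordinates."""
        xs = np.stack([tr.x for tr in self.trajectories])
        ys = np.stack([tr.y for tr in self.trajectories])
        return xs, ys

    def to_frame(self) -> pd.DataFrame:
        t = self.timebase.times
        rows = []
        for tr in self.trajectories:
            rows.append(
                pd.DataFrame(
                    {
                        "marker_id": tr.marker_id,
                        "frame": np.arange(tr.n_frames),
                        "t_s": t,
                        "x_px": tr.x,
                        "y_px": tr.y,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def write_trajectories(ts: TrajectorySet, path) -> None:
    """Write a trajectory set as CSV (`marker_id,frame,t_s,x_px,y_px`)."""
    ts.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path, syncytium_id: int = 0, condition: str = "CTRL",
                      minute: int = 0) -> TrajectorySet:
    """Read a trajectory CSV, validating the schema.

    Raises :class:`TrajectoryParseError` on missing columns, gaps in frame
    numbering, non-uniform time stamps or markers of unequal length.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")

    lengths = df.groupby("marker_id")["frame"].count()
    if lengths.nunique() != 1:
        raise TrajectoryParseError(
            f"{path}: markers have unequal frame counts "
            f"(min {lengths.min()}, max {lengths.max()})"
        )
    n_frames = int(lengths.iloc[0])

    trajectories = []
    fs = None
    for mid, g in df.groupby("marker_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        expected = np.arange(n_frames)
        if not np.array_equal(frames, expected):
            bad = int(expected[frames != expected][0]) if frames.size == n_frames \
                else int(frames.size)
            raise TrajectoryParseError(
                f"{path}: marker {mid} has a gap in frame numbering near frame {bad}"
            )
        t = g["t_s"].to_numpy()
        dt = np.diff(t)
        if t.size > 1 and (dt.min() <= 0 or np.ptp(dt) > 1e-6):
            raise TrajectoryParseError(
                f"{path}: marker {mid} has non-uniform time stamps"
            )
        fs = 1.0 / float(np.mean(dt)) if t.size > 1 else fs
        trajectories.append(
            MarkerTrajectory(int(mid), g["x_px"].to_numpy(), g["y_px"].to_numpy())
        )
    if fs is None:
        raise TrajectoryParseError(f"{path}: cannot infer sampling rate")
    tb = TimeBase(fs=round(fs, 9), n_frames=n_frames)
    return TrajectorySet(tb, trajectories, syncytium_id=syncytium_id,
                         condition=condition, minute=minute)
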