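"""Pose-track container and the multi-row-header CSV dialect.

Pose tracks are stored the way common markerless pose-estimation tools
emit them: a CSV with three header rows (track/scorer label, body-part
or landmark name, one of x|y|likelihood) and one data row per frame.
In memory a :class:`PoseTrack` wraps a DataFrame with a three-level
column MultiIndex and carries the frame rate and frame geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber import FRAME_SIZE, FPS_DEFAULT

__all__ = ["BODY_PARTS", "PoseTrack", "read_pose_csv", "write_pose_csv"]

#: The eight tracked body parts, nose to tail tip.
BODY_PARTS = (
    "nose",
    "left_ear",
    "right_ear",
    "neck_base",
    "body_centre",
    "tail_base",
    "tail_mid",
    "tail_tip",
)


@dataclass
class PoseTrack:
    """Frames x parts x (x, y, likelihood), plus landmark series.

    ``df`` columns are a MultiIndex (scorer, part, coord) with coord in
    {x, y, likelihood}. ``interpolated`` maps part name to a boolean
    per-frame array marking frames filled by :func:`clean_track`;
    ``unusable_parts`` lists parts with no valid frame at all.
    """

    df: pd.DataFrame
    fps: float = FPS_DEFAULT
    frame_size: tuple[int, int] = FRAME_SIZE
    interpolated: dict[str, np.ndarray] = field(default_factory=dict)
    unusable_parts: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.df.columns.nlevels != 3:
            raise ValueError("pose table needs a 3-level column index")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        lk = self.df.xs("likelihood", axis=1, level=2)
        with np.errstate(invalid="ignore"):
            vals = lk.to_numpy(float)
        if np.nanmin(vals, initial=1.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.df)

    @property
    def parts(self) -> list[str]:
        return list(dict.fromkeys(self.df.columns.get_level_values(1)))

    @property
    def scorer(self) -> str:
        return str(self.df.columns.get_level_values(0)[0])

    def part(self, name: str) -> pd.DataFrame:
        """The (x, y, likelihood) frame series of one part."""
        if name not in set(self.df.columns.get_level_values(1)):
            raise KeyError(f"no tracked part named {name!r}")
        sub = self.df.xs(name, axis=1, level=1)
        sub.columns = sub.columns.get_level_values(-1)
        return sub

    def xy(self, name: str) -> np.ndarray:
        p = self.part(name)
        return np.column_stack([p["x"].to_numpy(float), p["y"].to_numpy(float)])

    def likelihood(self, name: str) -> np.ndarray:
        return self.part(name)["likelihood"].to_numpy(float)

    def times(self) -> np.ndarray:
        """Frame start times on the video clock, seconds."""
        return np.arange(self.n_frames) / self.fps

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            df=self.df.copy(),
            fps=self.fps,
            frame_size=self.frame_size,
            interpolated={k: v.copy() for k, v in self.interpolated.items()},
            unusable_parts=set(self.unusable_parts),
        )


def write_pose_csv(track: PoseTrack, path: str | Path) -> None:
    track.df.to_csv(path, index_label="frame")


def read_pose_csv(
    path: str | Path,
    fps: float = FPS_DEFAULT,
    frame_size: tuple[int, int] = FRAME_SIZE,
) -> PoseTrack:
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    df.columns = df.columns.set_names(["scorer", "bodyparts", "coords"])
    return PoseTrack(df=df.astype(float).reset_index(drop=True), fps=fps,
                     frame_size=frame_size)
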