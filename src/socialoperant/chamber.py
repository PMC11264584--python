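"""Chamber landmark geometry for the operant box video frame.

Coordinates use the image convention: origin top-left, x rightward,
y downward, units of pixels in the default 928 x 576 frame recorded at
15 fps. Landmarks are the four floor corners, the food cup, the four
corners of the social door, the two extended-lever centres and the two
cue-light centres. An optional px-to-cm scale is derived from the floor
corners when the physical floor size is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

__all__ = ["ChamberLandmarks", "FRAME_SIZE", "FPS_DEFAULT", "default_landmarks"]

FRAME_SIZE = (928, 576)
FPS_DEFAULT = 15.0

Point = tuple[float, float]


@dataclass(frozen=True)
class ChamberLandmarks:
    """Static chamber geometry in frame pixels."""

    floor_corners: tuple[Point, Point, Point, Point]
    food_cup: Point
    door_corners: tuple[Point, Point, Point, Point]
    lever_centres: tuple[Point, Point]
    cue_light_centres: tuple[Point, Point]
    frame_size: tuple[int, int] = FRAME_SIZE
    floor_width_cm: float | None = None

    def __post_init__(self) -> None:
        w, h = self.frame_size
        for name in ("floor_corners", "door_corners"):
            for x, y in getattr(self, name):
                if not (0 <= x <= w and 0 <= y <= h):
                    raise ValueError(f"{name} point ({x}, {y}) outside frame")
        if not self.door_polygon.is_valid or self.door_polygon.area <= 0:
            raise ValueError("door_corners must form a simple quadrilateral")

    @property
    def door_polygon(self) -> Polygon:
        return Polygon(self.door_corners)

    @property
    def px_per_cm(self) -> float | None:
        """Scale from the mean horizontal floor edge, if calibrated."""
        if self.floor_width_cm is None:
            return None
        (x0, _), (x1, _), (x2, _), (x3, _) = self.floor_corners
        width_px = (abs(x1 - x0) + abs(x2 - x3)) / 2.0
        return width_px / self.floor_width_cm

    @property
    def part_names(self) -> dict[str, Point]:
        """Landmark name -> coordinate, matching pose-track columns."""
        fc = self.floor_corners
        dc = self.door_corners
        return {
            "floor_tl": fc[0],
            "floor_tr": fc[1],
            "floor_br": fc[2],
            "floor_bl": fc[3],
            "food_cup": self.food_cup,
            "door_tl": dc[0],
            "door_tr": dc[1],
            "door_br": dc[2],
            "door_bl": dc[3],
            "lever_active": self.lever_centres[0],
            "lever_inactive": self.lever_centres[1],
            "cue_active": self.cue_light_centres[0],
            "cue_inactive": self.cue_light_centres[1],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ChamberLandmarks":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))

        def pts(v):
            return tuple(tuple(float(c) for c in p) for p in v)

        return cls(
            floor_corners=pts(raw["floor_corners"]),
            food_cup=tuple(raw["food_cup"]),
            door_corners=pts(raw["door_corners"]),
            lever_centres=pts(raw["lever_centres"]),
            cue_light_centres=pts(raw["cue_light_centres"]),
            frame_size=tuple(raw.get("frame_size", FRAME_SIZE)),
            floor_width_cm=raw.get("floor_width_cm"),
        )


def default_landmarks() -> ChamberLandmarks:
    """A plausible chamber layout: door on the right wall, levers and
    cue lights on the left wall, floor inset from the frame edges."""
    return ChamberLandmarks(
        floor_corners=((110.0, 90.0), (820.0, 90.0), (820.0, 500.0), (110.0, 500.0)),
        food_cup=(130.0, 295.0),
        door_corners=((850.0, 250.0), (910.0, 250.0), (910.0, 340.0), (850.0, 340.0)),
        lever_centres=((230.0, 70.0), (430.0, 70.0)),
        cue_light_centres=((230.0, 35.0), (430.0, 35.0)),
    )
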