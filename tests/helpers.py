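"""Shared test utilities: track builders and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from socialoperant.pose_io import PoseTrack
from socialoperant.programs import SessionProgram


def make_track(parts: dict, fps: float = 15.0) -> PoseTrack:
    """Build a PoseTrack from {part: (x, y, likelihood)} arrays."""
    data = {}
    n = None
    for name, (x, y, lk) in parts.items():
        x, y, lk = (np.asarray(a, dtype=float) for a in (x, y, lk))
        n = len(x) if n is None else n
        assert len(x) == len(y) == len(lk) == n
        data[(name, "x")] = x
        data[(name, "y")] = y
        data[(name, "likelihood")] = lk
    cols = pd.MultiIndex.from_tuples(
        [("test", p, c) for (p, c) in data], names=["scorer", "bodyparts", "coords"]
    )
    df = pd.DataFrame(np.column_stack(list(data.values())), columns=cols)
    return PoseTrack(df=df, fps=fps)


def short_single_program(fr: int = 1, *, operant_s: float = 600.0,
                         pre_s: float = 60.0) -> SessionProgram:
    """A scaled-down between-session program (same rules, shorter)."""
    return SessionProgram(
        phase="2",
        fr_sequence=(fr,),
        reward_duration_s=30.0,
        iti_s=5.0,
        pre_period_s=pre_s,
        operant_duration_s=operant_s,
        retract_both_levers_on_reward=True,
    )


def point_in_polygon(x: float, y: float, corners) -> bool:
    """Independent ray-casting point-in-polygon oracle (strict interior
    for points off the edges; even-odd rule)."""
    inside = False
    pts = list(corners)
    j = len(pts) - 1
    for i in range(len(pts)):
        xi, yi = pts[i]
        xj, yj = pts[j]
        if (yi > y) != (yj > y):
            x_cross = (xj - xi) * (y - yi) / (yj - yi) + xi
            if x < x_cross:
                inside = not inside
        j = i
    return inside


def frame_overlap_oracle(iv_a, iv_b, span, step: float = 0.01) -> float:
    """Brute-force overlap duration by dense time enumeration."""
    ts = np.arange(span[0], span[1], step)
    in_a = np.zeros(ts.size, dtype=bool)
    for s, e in iv_a:
        in_a |= (ts >= s) & (ts < e)
    in_b = np.zeros(ts.size, dtype=bool)
    for s, e in iv_b:
        in_b |= (ts >= s) & (ts < e)
    return float(np.sum(in_a & in_b) * step)
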