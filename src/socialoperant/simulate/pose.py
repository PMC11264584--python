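"""Synthetic pose tracks emulating markerless tracking output.

Generates per-frame (x, y, likelihood) series at 15 fps in a 928 x 576
frame for the eight body parts and the static chamber landmarks, driven
by a session's event log:

* the body centre performs a clipped random walk on the floor and moves
  to the door during "engaged" open-door periods; the nose rides ahead
  of the body and is placed inside the door zone while engaged;
* cue-light likelihood exceeds 0.9 while the door is open and stays
  below 0.6 otherwise; lever likelihood exceeds 0.9 only once the
  levers have extended (session start) and drops during timeouts;
* random likelihood dropouts corrupt a configurable fraction of body
  frames (low likelihood + displaced coordinates);
* optional sub-second cue "blips" and an early lever blip are injected
  below the 1-s annotation rule and recorded in the ground truth as
  non-events, so event-inference precision/recall can be scored.

The generator emits its own ledger (true nose-in-door intervals, true
path length, true session start and door onsets on the video clock),
which is the oracle for the kinematics stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from ..chamber import ChamberLandmarks, FPS_DEFAULT
from ..events import OperantEventLog
from ..intervals import IntervalSet
from ..pose_io import BODY_PARTS, PoseTrack

__all__ = ["PoseNoiseConfig", "PoseTruth", "simulate_pose_track"]


@dataclass(frozen=True)
class PoseNoiseConfig:
    """Noise and scenario knobs for the pose generator."""

    dropout_rate: float = 0.05
    jitter_px: float = 1.0
    base_likelihood: float = 0.97
    nose_engage_prob: float = 0.9
    engage_decay_halflife_s: float | None = None
    n_cue_blips: int = 0
    cue_blip_duration_s: float = 0.5
    lever_blip_frames: int = 0
    video_offset_s: float = 0.0
    video_tail_s: float = 5.0
    walk_step_px: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not 0.0 <= self.nose_engage_prob <= 1.0:
            raise ValueError("nose_engage_prob must lie in [0, 1]")


@dataclass
class PoseTruth:
    """Generator ledger on the video clock (seconds from frame 0)."""

    nose_in_door: IntervalSet
    path_length_px: float
    session_start_s: float
    door_onsets_s: list[float]
    video_offset_s: float
    cue_blip_spans: list[tuple[float, float]] = field(default_factory=list)
    lever_blip_span: tuple[float, float] | None = None


def _likelihood_series(rng, n, base, high_mask=None):
    lk = np.clip(base + rng.normal(0.0, 0.01, n), 0.905, 1.0)
    if high_mask is not None:
        low = rng.uniform(0.1, 0.5, n)
        lk = np.where(high_mask, lk, low)
    return lk


def _sample_in_polygon(rng, poly: Polygon, n: int) -> np.ndarray:
    """Uniform points inside a polygon (rejection from a shrunk bbox)."""
    minx, miny, maxx, maxy = poly.bounds
    cx, cy = poly.centroid.x, poly.centroid.y
    out = np.empty((n, 2))
    filled = 0
    for _ in range(50):
        if filled >= n:
            break
        m = n - filled
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        ok = contains_xy(poly, xs, ys)
        k = int(ok.sum())
        out[filled : filled + k, 0] = xs[ok]
        out[filled : filled + k, 1] = ys[ok]
        filled += k
    out[filled:] = (cx, cy)
    return out


def simulate_pose_track(
    log: OperantEventLog,
    chamber: ChamberLandmarks,
    noise: PoseNoiseConfig = PoseNoiseConfig(),
    seed: int = 0,
    fps: float = FPS_DEFAULT,
) -> tuple[PoseTrack, PoseTruth]:
    """Generate a pose track for one session's event log."""
    rng = np.random.default_rng(seed)
    off = noise.video_offset_s
    session_end = log.session_end_s
    n = int(math.ceil((session_end + off + noise.video_tail_s) * fps))
    t = np.arange(n) / fps  # video clock

    # --- apparatus state on the video clock -----------------------------
    onsets = [float(o) + off for o in log.times("reward_onset")]
    closes = list(log.times("door_close") + off)
    open_iv = IntervalSet(
        (o, c) for o, c in zip(onsets, closes[: len(onsets)]) if o < c
    )
    start_s = log.levers_extend_time + off
    open_mask = np.zeros(n, dtype=bool)
    for s, e in open_iv:
        open_mask |= (t >= s) & (t < e)

    lever_mask = t >= start_s
    for ts, te in zip(log.times("timeout_start"), log.times("timeout_end")):
        lever_mask &= ~((t >= ts + off) & (t < te + off))

    # --- body-centre walk on the floor ----------------------------------
    fx0, fy0 = chamber.floor_corners[0]
    fx1 = chamber.floor_corners[1][0]
    fy1 = chamber.floor_corners[2][1]
    steps = rng.normal(0.0, noise.walk_step_px, size=(n, 2))
    body = np.empty((n, 2))
    body[0] = ((fx0 + fx1) / 2.0, (fy0 + fy1) / 2.0)
    for i in range(1, n):
        body[i] = body[i - 1] + steps[i]
        body[i, 0] = min(max(body[i, 0], fx0 + 10), fx1 - 10)
        body[i, 1] = min(max(body[i, 1], fy0 + 10), fy1 - 10)

    # engagement: per open interval, the rat investigates the door with
    # probability nose_engage_prob, optionally decaying across rewards
    door_poly = chamber.door_polygon
    dcx, dcy = door_poly.centroid.x, door_poly.centroid.y
    anchor = np.array([fx1 - 30.0, min(max(dcy, fy0 + 20), fy1 - 20)])
    engaged_mask = np.zeros(n, dtype=bool)
    for j, (s, e) in enumerate(open_iv):
        p = noise.nose_engage_prob
        if noise.engage_decay_halflife_s is not None:
            p *= 2.0 ** (-(s - start_s) / noise.engage_decay_halflife_s)
        if rng.random() < p:
            engaged_mask |= (t >= s) & (t < e)
    body[engaged_mask] = anchor + rng.normal(0.0, 3.0, size=(int(engaged_mask.sum()), 2))

    # nose: ahead of the body; inside the door zone while engaged
    heading = rng.normal(0.0, 1.0, size=(n, 2))
    norms = np.linalg.norm(heading, axis=1, keepdims=True)
    nose = body + 18.0 * heading / np.maximum(norms, 1e-9)
    nose[:, 0] = np.minimum(nose[:, 0], fx1 - 5)  # never drifts into the door zone
    n_eng = int(engaged_mask.sum())
    if n_eng:
        nose[engaged_mask] = _sample_in_polygon(rng, door_poly.buffer(-4.0), n_eng)

    true_path = float(np.sum(np.linalg.norm(np.diff(body, axis=0), axis=1)))
    nose_truth = IntervalSet.from_mask(engaged_mask, fps)

    # --- other body parts ride on the body centre -----------------------
    offsets = {
        "nose": None,  # handled above
        "left_ear": (-10.0, -12.0),
        "right_ear": (10.0, -12.0),
        "neck_base": (0.0, -8.0),
        "body_centre": (0.0, 0.0),
        "tail_base": (-2.0, 14.0),
        "tail_mid": (-4.0, 26.0),
        "tail_tip": (-6.0, 38.0),
    }

    data: dict[tuple[str, str], np.ndarray] = {}

    def add_part(name, xy, lk):
        jit = rng.normal(0.0, noise.jitter_px, size=xy.shape)
        data[(name, "x")] = xy[:, 0] + jit[:, 0]
        data[(name, "y")] = xy[:, 1] + jit[:, 1]
        data[(name, "likelihood")] = lk

    for part in BODY_PARTS:
        xy = nose.copy() if part == "nose" else body + np.asarray(offsets[part])
        lk = _likelihood_series(rng, n, noise.base_likelihood)
        if noise.dropout_rate > 0:
            drop = rng.random(n) < noise.dropout_rate
            lk = np.where(drop, rng.uniform(0.05, 0.5, n), lk)
            xy = xy.copy()
            xy[drop] += rng.uniform(-100.0, 100.0, size=(int(drop.sum()), 2))
        add_part(part, xy, lk)

    # --- landmarks ------------------------------------------------------
    truth = PoseTruth(
        nose_in_door=nose_truth,
        path_length_px=true_path,
        session_start_s=start_s,
        door_onsets_s=onsets,
        video_offset_s=off,
    )

    cue_mask = open_mask.copy()
    closed_times = np.flatnonzero(~open_mask & (t > start_s + 2.0))
    blip_len = max(1, int(round(noise.cue_blip_duration_s * fps)))
    guard = int(2 * fps)
    placed = 0
    attempts = 0
    while placed < noise.n_cue_blips and attempts < 200 and closed_times.size:
        attempts += 1
        i0 = int(rng.choice(closed_times))
        i1 = i0 + blip_len
        lo, hi = max(0, i0 - guard), min(n, i1 + guard)
        if i1 > n or open_mask[lo:hi].any() or cue_mask[lo:hi].any():
            continue
        cue_mask[i0:i1] = True
        truth.cue_blip_spans.append((t[i0], t[i1 - 1] + 1.0 / fps))
        placed += 1

    if noise.lever_blip_frames > 0:
        b0 = int(1.0 * fps)
        b1 = b0 + int(noise.lever_blip_frames)
        if t[min(b1, n - 1)] < start_s - 2.0:
            lever_mask = lever_mask.copy()
            lever_mask[b0:b1] = True
            truth.lever_blip_span = (t[b0], t[b1 - 1] + 1.0 / fps)

    for name, (lx, ly) in chamber.part_names.items():
        xy = np.tile([lx, ly], (n, 1)) + rng.normal(0.0, 0.5, size=(n, 2))
        if name == "cue_active":
            lk = _likelihood_series(rng, n, 0.96, cue_mask)
        elif name.startswith("lever"):
            lk = _likelihood_series(rng, n, 0.96, lever_mask)
        elif name == "cue_inactive":
            lk = rng.uniform(0.1, 0.5, n)
        else:
            lk = _likelihood_series(rng, n, noise.base_likelihood)
        data[(name, "x")] = xy[:, 0]
        data[(name, "y")] = xy[:, 1]
        data[(name, "likelihood")] = lk

    cols = pd.MultiIndex.from_tuples(
        [("sim", p, c) for (p, c) in data], names=["scorer", "bodyparts", "coords"]
    )
    df = pd.DataFrame(
        np.column_stack([data[k] for k in data]), columns=cols
    )
    track = PoseTrack(df=df, fps=fps, frame_size=chamber.frame_size)
    return track, truth
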