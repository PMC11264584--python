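"""Pose-track post-processing and apparatus-state inference.

The kinematic stage turns raw tracking tables into behavioural
outcomes without any manual video annotation:

* likelihood gating at 0.6 with linear interpolation of interior gaps
  (:func:`clean_track`);
* session-start detection from the first 1-s span in which both lever
  landmarks track with likelihood above 0.9 (the levers extending into
  the chamber are the first visible sign of the program starting);
* door-state inference from cue-light likelihood: each span above 0.9
  lasting at least 1 s marks a reward onset, and the door is open for
  the programmed 30- or 60-s period from that onset;
* nose-in-door-zone bouts by point-in-polygon membership against the
  door quadrilateral;
* occupancy summaries (time and proportion of open- and closed-door
  time with the nose in the door), locomotion path length, and
  alignment of the video clock to the operant event log for per-FR-bin
  summaries.

Sub-second likelihood "blips" are rejected by the duration gates, which
is what makes the inference robust to tracking noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .chamber import ChamberLandmarks
from .events import OperantEventLog
from .intervals import IntervalSet
from .pose_io import PoseTrack

__all__ = [
    "LIKELIHOOD_THRESHOLD",
    "CUE_THRESHOLD",
    "SessionStartNotFound",
    "AlignmentError",
    "clean_track",
    "detect_session_start",
    "infer_door_intervals",
    "nose_zone_intervals",
    "occupancy_summary",
    "locomotion_path_length",
    "align_to_fr_bins",
    "reward_ordinal_contrast",
]

LIKELIHOOD_THRESHOLD = 0.6
CUE_THRESHOLD = 0.9


class SessionStartNotFound(RuntimeError):
    """No qualifying dual-lever span: the video is unusable."""


class AlignmentError(RuntimeError):
    """Video and operant clocks disagree beyond tolerance."""


def _min_span_frames(fps: float) -> int:
    # "1 s" spans are >= ceil(fps) consecutive frames (non-strict).
    return int(math.ceil(fps))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as (start, stop) frame indices, stop exclusive."""
    if mask.size == 0 or not mask.any():
        return []
    edges = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def clean_track(
    track: PoseTrack, likelihood_threshold: float = LIKELIHOOD_THRESHOLD
) -> PoseTrack:
    """Gate coordinates by likelihood and interpolate the gaps.

    Frames with likelihood above the threshold pass through unchanged;
    interior gaps are filled by linear interpolation of x and y, and
    leading/trailing gaps by the nearest valid value (no
    extrapolation). Interpolated frames are flagged per part; a part
    with no valid frame at all is marked unusable and left untouched.
    The operation is idempotent because likelihoods are preserved and
    interpolation depends only on the valid frames.
    """
    if track.n_frames == 0:
        raise ValueError("empty track")
    out = track.copy()
    df = out.df
    scorer = out.scorer
    for part in out.parts:
        lk = out.likelihood(part)
        valid = lk > likelihood_threshold
        out.interpolated[part] = ~valid
        if not valid.any():
            out.unusable_parts.add(part)
            continue
        for coord in ("x", "y"):
            s = df[(scorer, part, coord)].astype(float)
            s = s.where(valid)
            s = s.interpolate(method="linear", limit_area="inside")
            s = s.ffill().bfill()
            df[(scorer, part, coord)] = s
    return out


def detect_session_start(track: PoseTrack, cue_threshold: float = CUE_THRESHOLD):
    """First time both levers track with high likelihood for >= 1 s.

    Returns ``(frame_index, time_s)`` on the video clock. Raises
    :class:`SessionStartNotFound` when no qualifying span exists.
    """
    both = (track.likelihood("lever_active") > cue_threshold) & (
        track.likelihood("lever_inactive") > cue_threshold
    )
    need = _min_span_frames(track.fps)
    for s, e in _runs(both):
        if e - s >= need:
            return s, s / track.fps
    raise SessionStartNotFound(
        "no 1-s span with both levers above the likelihood cut-off"
    )


def infer_door_intervals(
    track: PoseTrack,
    reward_duration_s: float,
    cue_parts: tuple[str, ...] = ("cue_active", "cue_inactive"),
    cue_threshold: float = CUE_THRESHOLD,
) -> IntervalSet:
    """Open-door periods inferred from cue-light likelihood.

    Each onset is the start of a span of cue likelihood above 0.9
    lasting at least 1 s; the door is open for ``reward_duration_s``
    from the onset. Onsets falling inside the open period of a previous
    onset are refractory-suppressed (the cue signals only the beginning
    of the period). Intervals are on the video clock.
    """
    if reward_duration_s <= 0:
        raise ValueError("reward_duration_s must be positive")
    lit = np.zeros(track.n_frames, dtype=bool)
    for part in cue_parts:
        if part in track.parts:
            lit |= track.likelihood(part) > cue_threshold
    need = _min_span_frames(track.fps)
    onsets = [s / track.fps for s, e in _runs(lit) if e - s >= need]
    accepted: list[float] = []
    for onset in onsets:
        if accepted and onset < accepted[-1] + reward_duration_s:
            continue
        accepted.append(onset)
    iv = IntervalSet((o, o + reward_duration_s) for o in accepted)
    if len(iv) != len(accepted):
        raise AssertionError("inferred door intervals overlap after suppression")
    return iv


def nose_zone_intervals(
    track: PoseTrack,
    landmarks: ChamberLandmarks,
    zone: Polygon | None = None,
    margin_px: float = 0.0,
    part: str = "nose",
) -> IntervalSet:
    """Bouts with the part inside the (dilated) zone polygon.

    The zone defaults to the door quadrilateral; ``margin_px`` dilates
    it. Frame membership is a point-in-polygon test; maximal runs of
    member frames become intervals on the video clock.
    """
    poly = zone if zone is not None else landmarks.door_polygon
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("zone polygon is degenerate")
    if margin_px:
        poly = poly.buffer(float(margin_px))
    if part in track.unusable_parts:
        raise ValueError(f"part {part!r} is unusable (no valid frames)")
    xy = track.xy(part)
    inside = contains_xy(poly, xy[:, 0], xy[:, 1])
    return IntervalSet.from_mask(inside, track.fps)


def occupancy_summary(
    nose_intervals: IntervalSet,
    door_intervals: IntervalSet,
    session_span: tuple[float, float],
) -> dict:
    """Nose-in-door time and proportions over open and closed door time.

    Proportions are ``None`` with a reason when their denominator is
    zero (a session with no rewards has no open-door time).
    """
    open_iv = door_intervals.clip(session_span)
    nose_iv = nose_intervals.clip(session_span)
    closed_iv = open_iv.complement(session_span)
    t_open = nose_iv.intersection(open_iv).total
    t_closed = nose_iv.intersection(closed_iv).total
    out = {
        "time_nose_open_door_s": t_open,
        "time_nose_closed_door_s": t_closed,
        "open_door_s": open_iv.total,
        "closed_door_s": closed_iv.total,
        "prop_open_door_nose": None,
        "prop_closed_door_nose": None,
        "missing_reason": None,
    }
    if open_iv.total > 0:
        out["prop_open_door_nose"] = t_open / open_iv.total
    else:
        out["missing_reason"] = "no open-door time (zero rewards)"
    if closed_iv.total > 0:
        out["prop_closed_door_nose"] = t_closed / closed_iv.total
    return out


def locomotion_path_length(
    track: PoseTrack,
    part: str = "body_centre",
    jitter_floor_px: float = 0.5,
    landmarks: ChamberLandmarks | None = None,
) -> dict:
    """Total path length of a part, ignoring sub-floor displacements.

    Per-frame Euclidean displacements below ``jitter_floor_px`` are
    treated as tracker jitter and contribute zero. Returns the length
    in px and, when the chamber is calibrated, in cm.
    """
    if part in track.unusable_parts:
        raise ValueError(f"part {part!r} is unusable (no valid frames)")
    xy = track.xy(part)
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    d = d[d >= jitter_floor_px]
    px = float(d.sum())
    out = {"path_length_px": px, "path_length_cm": None}
    if landmarks is not None and landmarks.px_per_cm:
        out["path_length_cm"] = px / landmarks.px_per_cm
    return out


def align_to_fr_bins(
    track: PoseTrack,
    log: OperantEventLog,
    nose_intervals: IntervalSet,
    door_intervals: IntervalSet,
    *,
    tolerance_s: float = 1.0,
) -> pd.DataFrame:
    """Shift the video clock onto the operant clock and summarise bins.

    The shift equates the detected session start (levers visible) with
    the log's lever-extension time. After shifting, every inferred door
    onset must land within ``tolerance_s`` of a logged reward onset,
    otherwise an :class:`AlignmentError` is raised. Returns one row per
    FR bin (or a single whole-session row for unbinned logs) with
    occupancy summaries and inferred reward counts on the session
    clock.
    """
    _, start_video = detect_session_start(track)
    shift = start_video - log.levers_extend_time
    nose = nose_intervals.shift(-shift)
    door = door_intervals.shift(-shift)

    logged = log.times("reward_onset")
    inferred = door.starts
    if inferred.size and logged.size:
        resid = np.abs(inferred[:, None] - logged[None, :]).min(axis=1)
        if np.any(resid > tolerance_s):
            raise AlignmentError(
                f"door onsets deviate from logged rewards by up to "
                f"{resid.max():.2f} s (> {tolerance_s} s)"
            )

    bins = log.bins()
    spans = (
        [(fr, s, e) for fr, s, e in bins]
        if bins
        else [(None, log.levers_extend_time, log.session_end_s)]
    )
    rows = []
    for fr, s, e in spans:
        summ = occupancy_summary(nose, door, (s, e))
        onsets_in = int(np.sum((inferred >= s) & (inferred < e)))
        rows.append({"fr": fr, "start_s": s, "end_s": e,
                     "rewards_inferred": onsets_in, **summ})
    out = pd.DataFrame(rows)
    out.attrs["clock_shift_s"] = shift
    return out


def reward_ordinal_contrast(
    nose_intervals: IntervalSet,
    door_intervals: IntervalSet,
    first_k: int = 3,
    last_k: int = 3,
) -> dict:
    """Nose-in-door proportion over the first-k vs last-k open periods.

    A drop from first to last is the kinematic signature of social
    satiety. Returns None proportions with a reason when fewer than
    ``first_k + last_k`` rewards were obtained.
    """
    if len(door_intervals) < first_k + last_k:
        return {
            "prop_first": None,
            "prop_last": None,
            "missing_reason": (
                f"only {len(door_intervals)} rewards; need {first_k + last_k}"
            ),
        }

    def prop(iv_list):
        sub = IntervalSet(iv_list)
        return nose_intervals.intersection(sub).total / sub.total

    ivs = list(door_intervals)
    return {
        "prop_first": prop(ivs[:first_k]),
        "prop_last": prop(ivs[-last_k:]),
        "missing_reason": None,
    }
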