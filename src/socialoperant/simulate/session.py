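"""Event-level simulation of social operant sessions.

Active presses arrive as a renewal process with exponential inter-press
intervals (a Poisson process, optionally thinned by an exponential
within-session satiety decay). The press rate is calibrated so that the
expected number of rewards in the responding window equals the
subject's exponential demand prediction Q(C) at the current price: if R
rewards each consume ``reward + ITI`` seconds, the remaining window
must host R x FR presses, giving rate = R*FR / (window - R*(reward+ITI)),
capped at the subject's physical maximum press rate. Inactive presses
are homogeneous Poisson at a low constant rate.

Reinforcement logic follows the fixed-ratio schedule exactly: the FR-th
active press since the previous reward opens the social door for the
programmed duration, followed by the ITI, during which the active lever
is unavailable. Within-session (binned) programs run the ascending FR
ladder in 5-min bins separated by 15-s timeouts, with the carry-over
rule: a reward earned within 30 s of a bin's end still receives its
full 30-s open-door period and the timeout is delayed accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..demand import predict_consumption
from ..events import OperantEventLog
from ..intervals import IntervalSet
from ..programs import SessionProgram
from .params import TrueSubjectParams

__all__ = ["SessionTruth", "SimulatedSession", "simulate_session"]

_RATE_FLOOR = 1e-9


@dataclass
class SessionTruth:
    """The simulator's own ledger for one session."""

    rewards: int
    active_presses: int
    inactive_presses: int
    latency_first_active_s: float | None
    reward_onsets: list[float]
    door_intervals: IntervalSet
    levers_extend_s: float
    session_end_s: float
    bin_rewards: list[tuple[int, int]] = field(default_factory=list)
    bin_spans: list[tuple[int, float, float]] = field(default_factory=list)


@dataclass
class SimulatedSession:
    log: OperantEventLog
    truth: SessionTruth


def _decay_factor(t: float, t0: float, halflife: float | None) -> float:
    if halflife is None:
        return 1.0
    return 2.0 ** (-(t - t0) / halflife)


def _press_rate(
    params: TrueSubjectParams,
    fr: int,
    window_s: float,
    reward_s: float,
    iti_s: float,
) -> float:
    """Press rate whose expected consumption matches the demand curve."""
    q_target = predict_consumption(
        params.q0_true, params.alpha_true, params.k_true, fr
    )
    cycle = reward_s + iti_s
    if cycle > 0:
        q_target = min(q_target, window_s / cycle)
    press_time = window_s - q_target * cycle
    if press_time <= window_s * 1e-9:
        return params.press_rate_base
    lam = q_target * fr / press_time
    return min(lam, params.press_rate_base)


class _PressGenerator:
    """Thinned-Poisson active-press stream at a bin-specific base rate."""

    def __init__(self, rng, t0: float, halflife: float | None):
        self.rng = rng
        self.t0 = t0
        self.halflife = halflife

    def next_press(self, t: float, lam: float, limit: float) -> float:
        if lam <= _RATE_FLOOR:
            return math.inf
        while t < limit:
            t += self.rng.exponential(1.0 / lam)
            if self.rng.random() < _decay_factor(t, self.t0, self.halflife):
                return t
        return math.inf


def simulate_session(
    params: TrueSubjectParams,
    program: SessionProgram,
    fr: int | None = None,
    seed: int = 0,
    *,
    subject_id: str | None = None,
    session_id: str = "sim",
) -> SimulatedSession:
    """Simulate one operant session; returns the event log + truth ledger.

    ``fr`` overrides the program's (single) FR requirement for
    single-schedule programs and must be omitted for binned programs,
    which use the program's ascending ladder.
    """
    rng = np.random.default_rng(seed)
    subject_id = subject_id or params.subject_id
    if program.is_binned:
        if fr is not None:
            raise ValueError("binned programs take their FR ladder from the program")
        return _simulate_binned(params, program, rng, subject_id, session_id)
    fr = int(fr) if fr is not None else int(program.fr_sequence[0])
    if fr <= 0:
        raise ValueError("FR must be a positive integer")
    return _simulate_single(params, program, fr, rng, subject_id, session_id)


def _inactive_times(rng, params, t0: float, t1: float) -> np.ndarray:
    if params.inactive_rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(params.inactive_rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _finish(events, subject_id, session_id, phase, fr, truth) -> SimulatedSession:
    ev = pd.DataFrame(events, columns=["time_s", "event", "value"])
    ev = ev.sort_values("time_s", kind="stable", ignore_index=True)
    log = OperantEventLog(
        subject_id=subject_id,
        session_id=session_id,
        phase=phase,
        events=ev,
        fr=fr,
    )
    return SimulatedSession(log=log, truth=truth)


def _simulate_single(
    params, program, fr, rng, subject_id, session_id
) -> SimulatedSession:
    t0 = program.pre_period_s
    end = t0 + program.operant_duration_s
    lam = _press_rate(
        params, fr, program.operant_duration_s,
        program.reward_duration_s, program.iti_s,
    )
    gen = _PressGenerator(rng, t0, params.satiety_halflife_s)

    events: list[tuple[float, str, float]] = [
        (0.0, "session_start", np.nan),
        (t0, "levers_extend", np.nan),
    ]
    onsets: list[float] = []
    active = 0
    presses_since = 0
    first_press: float | None = None
    t = t0
    while True:
        tp = gen.next_press(t, lam, end)
        if tp >= end:
            break
        active += 1
        presses_since += 1
        if first_press is None:
            first_press = tp
        events.append((tp, "active_press", np.nan))
        if presses_since == fr:
            onsets.append(tp)
            events.append((tp, "reward_onset", float(len(onsets))))
            close = tp + program.reward_duration_s
            events.append((close, "door_close", np.nan))
            presses_since = 0
            t = close + program.iti_s
        else:
            t = tp

    inact = _inactive_times(rng, params, t0, end)
    events.extend((ti, "inactive_press", np.nan) for ti in inact)

    truth = SessionTruth(
        rewards=len(onsets),
        active_presses=active,
        inactive_presses=int(inact.size),
        latency_first_active_s=None if first_press is None else first_press - t0,
        reward_onsets=onsets,
        door_intervals=IntervalSet(
            (o, o + program.reward_duration_s) for o in onsets
        ),
        levers_extend_s=t0,
        session_end_s=end,
    )
    return _finish(events, subject_id, session_id, program.phase, fr, truth)


def _simulate_binned(params, program, rng, subject_id, session_id) -> SimulatedSession:
    t0 = program.pre_period_s
    bin_dur = program.bin_duration_s
    ifi = program.inter_fr_interval_s or 0.0
    rd = program.reward_duration_s
    gen = _PressGenerator(rng, t0, params.satiety_halflife_s)

    events: list[tuple[float, str, float]] = [
        (0.0, "session_start", np.nan),
        (t0, "levers_extend", np.nan),
    ]
    onsets: list[float] = []
    bin_rewards: list[tuple[int, int]] = []
    bin_spans: list[tuple[int, float, float]] = []
    active = 0
    first_press: float | None = None
    t_bin = t0
    last = len(program.fr_sequence) - 1
    for i, fr in enumerate(program.fr_sequence):
        sched_end = t_bin + bin_dur
        events.append((t_bin, "bin_start", float(fr)))
        lam = _press_rate(params, fr, bin_dur, rd, program.iti_s)
        t = t_bin
        presses_since = 0
        n_bin = 0
        bin_end_actual = sched_end
        while True:
            tp = gen.next_press(t, lam, sched_end)
            if tp >= sched_end:
                break
            active += 1
            presses_since += 1
            if first_press is None:
                first_press = tp
            events.append((tp, "active_press", np.nan))
            if presses_since == fr:
                onsets.append(tp)
                n_bin += 1
                events.append((tp, "reward_onset", float(len(onsets))))
                close = tp + rd
                events.append((close, "door_close", np.nan))
                presses_since = 0
                t = close + program.iti_s
                if close > sched_end:  # carry-over: full reward honoured
                    bin_end_actual = close
            else:
                t = tp
        events.append((bin_end_actual, "bin_end", float(fr)))
        bin_rewards.append((fr, n_bin))
        bin_spans.append((fr, t_bin, bin_end_actual))
        if i < last:
            events.append((bin_end_actual, "timeout_start", np.nan))
            events.append((bin_end_actual + ifi, "timeout_end", np.nan))
            t_bin = bin_end_actual + ifi
    session_end = bin_spans[-1][2]

    inact = _inactive_times(rng, params, t0, session_end)
    events.extend((ti, "inactive_press", np.nan) for ti in inact)

    truth = SessionTruth(
        rewards=len(onsets),
        active_presses=active,
        inactive_presses=int(inact.size),
        latency_first_active_s=None if first_press is None else first_press - t0,
        reward_onsets=onsets,
        door_intervals=IntervalSet((o, o + rd) for o in onsets),
        levers_extend_s=t0,
        session_end_s=session_end,
        bin_rewards=bin_rewards,
        bin_spans=bin_spans,
    )
    return _finish(events, subject_id, session_id, program.phase, None, truth)
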