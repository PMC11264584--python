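"""Operant event logs: the timestamped record of one subject-session.

Each session is a CSV with columns ``time_s, event, value`` and one row
per event (lever presses, reward onsets, door closures, FR-bin
boundaries, timeouts). Times are seconds from session start at
millisecond resolution. This is the interchange format between the
simulator, the outcome extraction stage, and the kinematic alignment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "OperantEventLog",
    "EventLogError",
    "read_event_log",
    "write_event_log",
]

EVENT_TYPES = (
    "session_start",
    "levers_extend",
    "active_press",
    "inactive_press",
    "reward_onset",
    "door_close",
    "bin_start",
    "bin_end",
    "timeout_start",
    "timeout_end",
)

_COLUMNS = ["time_s", "event", "value"]


class EventLogError(ValueError):
    """Raised for malformed or invariant-violating event logs."""


@dataclass
class OperantEventLog:
    """Time-ordered event stream for one subject-session.

    ``events`` is a DataFrame with columns ``time_s`` (float, seconds),
    ``event`` (str) and ``value`` (float or NaN; carries the FR value on
    ``bin_start`` rows).
    """

    subject_id: str
    session_id: str
    phase: str
    events: pd.DataFrame = field(repr=False)
    fr: int | None = None

    def __post_init__(self) -> None:
        ev = self.events
        missing = [c for c in _COLUMNS if c not in ev.columns]
        if missing:
            raise EventLogError(f"event table missing columns {missing}")
        self.events = ev = ev[_COLUMNS].reset_index(drop=True)
        ev["time_s"] = ev["time_s"].astype(float).round(3)
        ev["value"] = pd.to_numeric(ev["value"], errors="coerce")

    # -- queries ---------------------------------------------------------
    def times(self, event: str) -> np.ndarray:
        return self.events.loc[self.events["event"] == event, "time_s"].to_numpy()

    def count(self, event: str) -> int:
        return int((self.events["event"] == event).sum())

    @property
    def levers_extend_time(self) -> float:
        t = self.times("levers_extend")
        if t.size == 0:
            raise EventLogError("log has no levers_extend event")
        return float(t[0])

    @property
    def session_end_s(self) -> float:
        return float(self.events["time_s"].max())

    def bins(self) -> list[tuple[int, float, float]]:
        """(fr, start_s, end_s) for each FR bin, in order; [] if unbinned."""
        starts = self.events[self.events["event"] == "bin_start"]
        ends = self.times("bin_end")
        if len(starts) != len(ends):
            raise EventLogError("unbalanced bin_start/bin_end events")
        return [
            (int(v), float(t), float(e))
            for t, v, e in zip(starts["time_s"], starts["value"], ends)
        ]

    # -- validation ------------------------------------------------------
    def validate(self, fr: int | None = None) -> None:
        """Check ordering and schedule invariants; raise EventLogError.

        When an FR value is known (argument or ``self.fr``), every
        reward onset must be preceded — since the previous reward — by
        at least FR active presses.
        """
        ev = self.events
        unknown = set(ev["event"]) - set(EVENT_TYPES)
        if unknown:
            raise EventLogError(f"unknown event types: {sorted(unknown)}")
        t = ev["time_s"].to_numpy()
        if t.size and np.any(np.diff(t) < 0):
            row = int(np.flatnonzero(np.diff(t) < 0)[0]) + 2  # 1-based + header
            raise EventLogError(f"non-monotone time at data row {row}")
        if self.count("session_start") != 1:
            raise EventLogError("log must contain exactly one session_start")
        fr = fr if fr is not None else self.fr
        if fr is not None and not self.bins():
            presses_since = 0
            for row in ev.itertuples(index=False):
                if row.event == "active_press":
                    presses_since += 1
                elif row.event == "reward_onset":
                    if presses_since < fr:
                        raise EventLogError(
                            f"reward at t={row.time_s} after only "
                            f"{presses_since} active presses (FR {fr})"
                        )
                    presses_since = 0


def write_event_log(log: OperantEventLog, path: str | Path) -> None:
    log.events.to_csv(path, index=False, columns=_COLUMNS)


def read_event_log(
    path: str | Path,
    *,
    subject_id: str | None = None,
    session_id: str | None = None,
    phase: str = "",
    fr: int | None = None,
    validate: bool = True,
) -> OperantEventLog:
    """Read and validate an event-log CSV.

    Subject/session identity is not stored in the CSV itself (it lives
    in the bundle manifest); by default both are taken from the file
    stem ``<subject>_<session>.csv``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    try:
        ev = pd.read_csv(io.StringIO(text), dtype={"event": str})
    except Exception as exc:  # malformed CSV
        raise EventLogError(f"{path.name}: cannot parse CSV ({exc})") from exc
    if list(ev.columns) != _COLUMNS:
        raise EventLogError(
            f"{path.name}: header must be {_COLUMNS}, got {list(ev.columns)}"
        )
    bad_time = pd.to_numeric(ev["time_s"], errors="coerce").isna()
    if bad_time.any():
        row = int(bad_time.idxmax()) + 2
        raise EventLogError(f"{path.name}: malformed time_s at data row {row}")
    ev["time_s"] = ev["time_s"].astype(float)
    if subject_id is None or session_id is None:
        stem = path.stem
        subject_id = subject_id or stem.split("_")[0]
        session_id = session_id or stem.partition("_")[2] or stem
    log = OperantEventLog(
        subject_id=subject_id,
        session_id=session_id,
        phase=phase,
        events=ev,
        fr=fr,
    )
    if validate:
        log.validate(fr=fr)
    return log
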