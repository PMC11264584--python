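"""Session programs for the social operant conditioning phases.

A :class:`SessionProgram` bundles the timing constants of one operant
session type: how long the social door stays open after a reward, the
inter-trial interval, the pre-session habituation period, and — for the
within-session economics phase — the fixed-ratio (FR) bin schedule.

The phase defaults reproduce the three-phase protocol of the social
operant model: acquisition at FR1 with 60-s social rewards and 20-s ITIs
(Phase 1), daily between-session price escalation with 30-s rewards and
5-s ITIs (Phase 2), and a single-session ascending FR ladder of 5-min
bins separated by 15-s timeouts (Phase 3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "SessionProgram",
    "PHASE1A",
    "PHASE1B",
    "PHASE2",
    "PHASE3",
    "PHASE2_FR_SESSIONS",
    "FR_LADDER",
    "phase2_program",
]

#: Ascending fixed-ratio price ladder used by Phases 2 and 3.
FR_LADDER: tuple[int, ...] = (1, 2, 4, 6, 9, 12)

#: Phase 2 session-by-session FR schedule: 3 sessions at FR1, 3 at FR2,
#: 4 at FR4, 3 each at FR6, FR9 and FR12 (19 daily sessions).
PHASE2_FR_SESSIONS: tuple[int, ...] = (
    1, 1, 1, 2, 2, 2, 4, 4, 4, 4, 6, 6, 6, 9, 9, 9, 12, 12, 12
)


@dataclass(frozen=True)
class SessionProgram:
    """Timing constants of one operant session type.

    Parameters
    ----------
    phase
        Protocol phase label: ``"1a"``, ``"1b"``, ``"2"`` or ``"3"``.
    fr_sequence
        FR requirement(s). A single value for Phases 1–2; the ascending
        bin ladder for Phase 3.
    reward_duration_s
        Open-door (social access) period following each earned reward.
    iti_s
        Inter-trial interval after the door closes.
    pre_period_s
        Habituation period before the levers extend.
    operant_duration_s
        Length of the responding window, measured from lever extension.
    bin_duration_s
        Duration of each FR bin (Phase 3 only).
    inter_fr_interval_s
        Timeout between consecutive FR bins (Phase 3 only).
    active_lever_retract_s
        Delay after reward delivery before the active lever retracts
        (Phase 1); ``None`` when not applicable.
    retract_both_levers_on_reward
        Whether both levers retract immediately on reward delivery
        (Phase 2 rule).
    """

    phase: str
    fr_sequence: tuple[int, ...]
    reward_duration_s: float
    iti_s: float
    pre_period_s: float = 600.0
    operant_duration_s: float = 3600.0
    bin_duration_s: float | None = None
    inter_fr_interval_s: float | None = None
    active_lever_retract_s: float | None = None
    retract_both_levers_on_reward: bool = False

    def __post_init__(self) -> None:
        durations = (
            self.reward_duration_s,
            self.iti_s,
            self.pre_period_s,
            self.operant_duration_s,
        )
        if any(d < 0 for d in durations):
            raise ValueError("session program durations must be >= 0")
        if not self.fr_sequence or any(
            f <= 0 or int(f) != f for f in self.fr_sequence
        ):
            raise ValueError("fr_sequence must contain positive integers")
        if self.bin_duration_s is not None and self.bin_duration_s <= 0:
            raise ValueError("bin_duration_s must be positive when set")
        if self.bin_duration_s is None and len(self.fr_sequence) > 1:
            raise ValueError("a multi-FR schedule requires bin_duration_s")

    @property
    def is_binned(self) -> bool:
        """True for within-session (binned) economics programs."""
        return self.bin_duration_s is not None

    @property
    def session_end_s(self) -> float:
        """Nominal session end (pre-period + responding window or bins)."""
        if self.is_binned:
            n = len(self.fr_sequence)
            ifi = self.inter_fr_interval_s or 0.0
            return self.pre_period_s + n * self.bin_duration_s + (n - 1) * ifi
        return self.pre_period_s + self.operant_duration_s


PHASE1A = SessionProgram(
    phase="1a",
    fr_sequence=(1,),
    reward_duration_s=60.0,
    iti_s=20.0,
    active_lever_retract_s=5.0,
)

PHASE1B = replace(PHASE1A, phase="1b")

PHASE2 = SessionProgram(
    phase="2",
    fr_sequence=(1,),
    reward_duration_s=30.0,
    iti_s=5.0,
    retract_both_levers_on_reward=True,
)

PHASE3 = SessionProgram(
    phase="3",
    fr_sequence=FR_LADDER,
    reward_duration_s=30.0,
    iti_s=0.0,
    operant_duration_s=6 * 300.0 + 5 * 15.0,
    bin_duration_s=300.0,
    inter_fr_interval_s=15.0,
    retract_both_levers_on_reward=True,
)


def phase2_program(fr: int) -> SessionProgram:
    """Phase 2 program for one daily session at a single FR price."""
    if fr <= 0:
        raise ValueError("FR must be a positive integer")
    return replace(PHASE2, fr_sequence=(int(fr),))
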