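"""Lever-press-derived outcomes and cohort filtering rules.

From each session's event log this stage extracts the operant outcomes
of interest — social rewards obtained, active and inactive lever
presses, their difference, and the latency to the first active press —
plus the within-session reward time course. Cohort rules live here
too: the top-50%-of-responders selection applied between the
acquisition and economics phases, and the paired oestrus-category
aggregation (P/O vs M/D means per subject).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import OperantEventLog

logger = logging.getLogger(__name__)

__all__ = [
    "SessionOutcomes",
    "session_outcomes",
    "outcomes_frame",
    "within_session_timecourse",
    "phase3_bin_rewards",
    "select_top_responders",
    "dichotomise_oestrus",
    "oestrus_paired_aggregate",
]

OESTRUS_PHASES = ("proestrus", "oestrus", "metoestrus", "dioestrus")
PO_PHASES = frozenset({"proestrus", "oestrus"})


@dataclass(frozen=True)
class SessionOutcomes:
    """Operant outcomes for one subject-session.

    Latency runs from lever extension to the first active press; a
    session with no active press is censored at the operant duration.
    ``log10_latency`` is the base-10 log, defined only for positive
    latencies (any base is monotone-equivalent downstream).
    """

    subject_id: str
    session_id: str
    rewards: int
    active_presses: int
    inactive_presses: int
    latency_first_active_s: float
    latency_censored: bool

    @property
    def active_minus_inactive(self) -> int:
        return self.active_presses - self.inactive_presses

    @property
    def log10_latency(self) -> float:
        if self.latency_first_active_s <= 0:
            return float("nan")
        return math.log10(self.latency_first_active_s)


def session_outcomes(
    log: OperantEventLog, operant_duration_s: float | None = None
) -> SessionOutcomes:
    """Counts and latency for one session.

    Rewards are counted by ``reward_onset`` events (a reward truncated
    by session end still counts). ``operant_duration_s`` sets the
    censoring value for sessions without an active press; when omitted
    it is taken as the span from lever extension to the last event.
    """
    t0 = log.levers_extend_time
    active_t = log.times("active_press")
    if active_t.size:
        latency = float(active_t[0] - t0)
        censored = False
    else:
        if operant_duration_s is None:
            operant_duration_s = log.session_end_s - t0
        latency = float(operant_duration_s)
        censored = True
    return SessionOutcomes(
        subject_id=log.subject_id,
        session_id=log.session_id,
        rewards=log.count("reward_onset"),
        active_presses=int(active_t.size),
        inactive_presses=log.count("inactive_press"),
        latency_first_active_s=latency,
        latency_censored=censored,
    )


def outcomes_frame(rows: list[tuple[OperantEventLog, dict]]) -> pd.DataFrame:
    """Tidy per-session outcome table from (log, metadata) pairs.

    Metadata dicts (phase, fr, condition, ...) are spliced into the
    row. One row per subject-session.
    """
    records = []
    for log, meta in rows:
        o = session_outcomes(log, meta.get("operant_duration_s"))
        records.append(
            {
                "subject_id": o.subject_id,
                "session_id": o.session_id,
                "phase": meta.get("phase", log.phase),
                "fr": meta.get("fr", log.fr),
                "condition": meta.get("condition"),
                "rewards": o.rewards,
                "active_presses": o.active_presses,
                "inactive_presses": o.inactive_presses,
                "active_minus_inactive": o.active_minus_inactive,
                "latency_first_active_s": o.latency_first_active_s,
                "latency_censored": o.latency_censored,
                "log10_latency": o.log10_latency,
            }
        )
    return pd.DataFrame(records)


def within_session_timecourse(
    log: OperantEventLog,
    bin_width_s: float,
    operant_duration_s: float | None = None,
) -> pd.DataFrame:
    """Rewards per consecutive time bin from lever extension.

    Bin counts sum to the session's total rewards; a final partial bin
    (when the bin width does not divide the window) is flagged.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    t0 = log.levers_extend_time
    if operant_duration_s is None:
        operant_duration_s = log.session_end_s - t0
    onsets = log.times("reward_onset") - t0
    n_bins = int(math.ceil(operant_duration_s / bin_width_s - 1e-9))
    edges = np.arange(n_bins + 1) * bin_width_s
    edges[-1] = max(edges[-1], operant_duration_s)
    counts, _ = np.histogram(onsets, bins=edges)
    partial = not math.isclose(
        n_bins * bin_width_s, operant_duration_s, rel_tol=0, abs_tol=1e-9
    )
    out = pd.DataFrame(
        {
            "bin_start_s": edges[:-1],
            "bin_end_s": edges[1:],
            "rewards": counts,
            "partial": [False] * (n_bins - 1) + [partial] if n_bins else [],
        }
    )
    return out


def phase3_bin_rewards(log: OperantEventLog) -> pd.DataFrame:
    """Rewards attributed to each FR bin of a within-session log."""
    bins = log.bins()
    if not bins:
        raise ValueError(f"session {log.session_id} has no FR bins")
    onsets = log.times("reward_onset")
    rows = []
    for fr, s, e in bins:
        rows.append(
            {
                "fr": fr,
                "bin_start_s": s,
                "bin_end_s": e,
                "rewards": int(np.sum((onsets >= s) & (onsets < e))),
            }
        )
    return pd.DataFrame(rows)


def select_top_responders(
    phase1_rewards: pd.DataFrame, designs: pd.DataFrame
) -> pd.DataFrame:
    """Top 50% of responders per Sex x Housing x ToD x chamber cell.

    ``phase1_rewards`` is tidy (subject_id, rewards) over the
    acquisition sessions. Within each cell, subjects are ranked by
    their mean rewards (descending, ties broken by ascending
    subject_id) and the top ceil(n/2) are retained; odd cells trigger a
    warning-level log entry. Returns the retained design rows.
    """
    means = phase1_rewards.groupby("subject_id")["rewards"].mean()
    missing = set(designs["subject_id"]) - set(means.index)
    if missing:
        raise ValueError(f"subjects without acquisition sessions: {sorted(missing)}")
    df = designs.copy()
    df["mean_rewards"] = df["subject_id"].map(means)
    kept = []
    for key, cell in df.groupby(["sex", "housing", "tod", "chamber_id"]):
        n = len(cell)
        n_keep = math.ceil(n / 2)
        if n % 2:
            logger.warning("cell %s has odd size %d; retaining %d", key, n, n_keep)
        ranked = cell.sort_values(
            ["mean_rewards", "subject_id"], ascending=[False, True], kind="stable"
        )
        kept.append(ranked.head(n_keep))
    out = pd.concat(kept) if kept else df.iloc[:0]
    return out.sort_values("subject_id", ignore_index=True)


def dichotomise_oestrus(records: pd.DataFrame) -> pd.DataFrame:
    """Map cycle phases to the P/O vs M/D hormone-level categories."""
    bad = set(records["phase_label"]) - set(OESTRUS_PHASES)
    if bad:
        raise ValueError(f"unknown oestrus phase labels: {sorted(bad)}")
    out = records.copy()
    out["category"] = np.where(
        out["phase_label"].isin(PO_PHASES), "P/O", "M/D"
    )
    return out


def oestrus_paired_aggregate(
    outcomes: pd.DataFrame,
    oestrus: pd.DataFrame,
    value_col: str = "rewards",
) -> pd.DataFrame:
    """Per-subject (P/O mean, M/D mean) pairs over labelled sessions.

    Outcomes are averaged within each oestrus category; subjects
    lacking either category are excluded (paired analyses only) and
    logged. ``oestrus`` needs columns subject_id, session_id and either
    category or phase_label.
    """
    oes = oestrus.copy()
    if "category" not in oes.columns:
        oes = dichotomise_oestrus(oes)
    merged = outcomes.merge(
        oes[["subject_id", "session_id", "category"]],
        on=["subject_id", "session_id"],
        how="inner",
    )
    wide = (
        merged.groupby(["subject_id", "category"])[value_col]
        .mean()
        .unstack("category")
        .reindex(columns=["P/O", "M/D"])
    )
    incomplete = wide.index[wide.isna().any(axis=1)]
    for sid in incomplete:
        logger.info("subject %s lacks one oestrus category; excluded from pairs", sid)
    out = wide.dropna().reset_index()
    out.columns = ["subject_id", "po_mean", "md_mean"]
    return out
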