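"""Full-cohort dataset bundles: designs, event logs, pose, ground truth.

:func:`generate_cohort` writes one self-consistent directory tree of
CSV/JSON files for a simulated study — the three-phase session
structure (8 + 1 acquisition sessions, the 19-session between-session
price ladder, 4 + 4 within-session sessions per stimulus-sex
condition), oestrus labels for females, and the generator's complete
ground truth — so every analysis stage can be run end-to-end against
known answers. Bundles are written atomically (a partial failure
leaves nothing behind) and are byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ..chamber import default_landmarks
from ..design import SubjectDesign, designs_to_frame, factorial_design
from ..events import write_event_log
from ..pose_io import write_pose_csv
from ..programs import (
    PHASE1A,
    PHASE1B,
    PHASE2_FR_SESSIONS,
    PHASE3,
    phase2_program,
)
from .params import (
    CohortGroundTruth,
    EffectScenario,
    female_isolation_scenario,
    sample_cohort_params,
)
from .pose import PoseNoiseConfig, simulate_pose_track
from .session import simulate_session

__all__ = ["CohortConfig", "CohortBundle", "generate_cohort"]

OESTRUS_CYCLE = ("proestrus", "oestrus", "metoestrus", "dioestrus")


@dataclass(frozen=True)
class CohortConfig:
    """What to simulate and at which scale."""

    n_per_cell: int = 2
    chambers_per_cell: int = 2
    phases: tuple[str, ...] = ("1a", "2", "3")
    scenario: EffectScenario = field(default_factory=female_isolation_scenario)
    n_phase1_sessions: int = 8
    opposite_alpha_multiplier: float = 0.6
    within_session_q0_fraction: float = 0.35
    satiety_halflife_s: float | None = None
    pose_for: tuple[str, ...] = ()  # phases that also get pose tracks
    pose_sessions_per_subject: int | None = None  # cap pose files per subject
    pose_noise: PoseNoiseConfig = field(default_factory=PoseNoiseConfig)


@dataclass
class CohortBundle:
    """In-memory index of a written bundle."""

    root: Path
    designs: pd.DataFrame
    sessions: pd.DataFrame
    truth: CohortGroundTruth | None
    manifest: dict


def _session_seed(base: int, subject_idx: int, session_idx: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(base), subject_idx, session_idx])


def _oestrus_labels(rng: np.random.Generator, n_sessions: int) -> list[str]:
    """A 4-day cycle sampled every other day from a random offset.

    Stepping 2 days through a 4-phase cycle alternates between one
    high-hormone (P/O) and one low-hormone (M/D) phase, so both
    categories always occur across the sessions.
    """
    offset = int(rng.integers(0, 4))
    return [OESTRUS_CYCLE[(offset + 2 * i) % 4] for i in range(n_sessions)]


def _phase_sessions(cfg: CohortConfig):
    """(phase, session_id, program, fr, condition) in protocol order."""
    plan = []
    if "1a" in cfg.phases:
        for i in range(cfg.n_phase1_sessions):
            plan.append(("1a", f"p1a-{i + 1:02d}", PHASE1A, 1, None))
    if "1b" in cfg.phases:
        plan.append(("1b", "p1b-09", PHASE1B, 1, None))
    if "2" in cfg.phases:
        for i, fr in enumerate(PHASE2_FR_SESSIONS):
            plan.append(("2", f"p2-{i + 1:02d}-fr{fr:02d}", phase2_program(fr), fr, None))
    if "3" in cfg.phases:
        for i in range(8):
            cond = "same" if i < 4 else "opposite"
            plan.append(("3", f"p3-{i + 1:02d}-{cond}", PHASE3, None, cond))
    return plan


def generate_cohort(
    config: CohortConfig,
    seed: int,
    out_dir: str | Path,
    designs: list[SubjectDesign] | None = None,
) -> CohortBundle:
    """Simulate and write a cohort bundle under ``out_dir``.

    The directory is created atomically: everything is staged in a
    sibling temp directory and moved into place only on success.
    """
    out_dir = Path(out_dir)
    if out_dir.exists():
        raise FileExistsError(f"{out_dir} already exists")
    stage = out_dir.with_name(out_dir.name + ".staging")
    if stage.exists():
        shutil.rmtree(stage)
    try:
        bundle = _generate_into(config, seed, stage, designs)
        stage.rename(out_dir)
        bundle.root = out_dir
    except BaseException:
        shutil.rmtree(stage, ignore_errors=True)
        raise
    return bundle


def _generate_into(config, seed, root: Path, designs) -> CohortBundle:
    (root / "events").mkdir(parents=True)
    if designs is None:
        designs = factorial_design(config.n_per_cell, config.chambers_per_cell)
    design_df = designs_to_frame(designs)
    design_df.to_csv(root / "designs.csv", index=False)

    truth = None
    experimental = [d for d in designs if d.role == "experimental"]
    if experimental:
        truth = sample_cohort_params(designs, config.scenario, seed)
        (root / "ground_truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1), encoding="utf-8"
        )

    plan = _phase_sessions(config)
    landmarks = default_landmarks()
    if config.pose_for:
        (root / "pose").mkdir()
        landmarks.to_json(root / "landmarks.json")

    session_rows = []
    truth_bin_rows = []
    oestrus_rows = []
    label_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    for si, d in enumerate(experimental):
        p = truth[d.subject_id]
        if config.satiety_halflife_s is not None:
            p = replace(p, satiety_halflife_s=config.satiety_halflife_s)
        p3_labels = _oestrus_labels(label_rng, 8) if d.sex == "F" else None
        p3_count = 0
        pose_count = 0
        for ki, (phase, sess_id, program, fr, cond) in enumerate(plan):
            sp = p
            if phase == "3":
                q0_bin = p.q0_true * config.within_session_q0_fraction
                alpha = p.alpha_true
                if cond == "opposite":
                    alpha *= config.opposite_alpha_multiplier
                sp = replace(p, q0_true=q0_bin, alpha_true=alpha)
            ss = _session_seed(seed, si, ki)
            sim = simulate_session(
                sp, program, fr=fr,
                seed=ss,
                subject_id=d.subject_id, session_id=sess_id,
            )
            fname = f"{d.subject_id}_{sess_id}.csv"
            write_event_log(sim.log, root / "events" / fname)
            t = sim.truth
            session_rows.append(
                {
                    "subject_id": d.subject_id,
                    "session_id": sess_id,
                    "phase": phase,
                    "fr": fr,
                    "condition": cond,
                    "events_file": f"events/{fname}",
                    "pose_file": None,
                    "true_rewards": t.rewards,
                    "true_active": t.active_presses,
                    "true_inactive": t.inactive_presses,
                    "true_latency_s": t.latency_first_active_s,
                }
            )
            for bfr, br in t.bin_rewards:
                truth_bin_rows.append(
                    {
                        "subject_id": d.subject_id,
                        "session_id": sess_id,
                        "fr": bfr,
                        "true_rewards": br,
                    }
                )
            if phase == "3" and p3_labels is not None:
                oestrus_rows.append(
                    {
                        "subject_id": d.subject_id,
                        "session_id": sess_id,
                        "phase_label": p3_labels[p3_count],
                    }
                )
            if phase == "3":
                p3_count += 1
            cap = config.pose_sessions_per_subject
            if phase in config.pose_for and (cap is None or pose_count < cap):
                pose_count += 1
                track, _ = simulate_pose_track(
                    sim.log, landmarks, config.pose_noise,
                    seed=np.random.SeedSequence([seed, 11, si, ki]),
                )
                pname = f"pose/{d.subject_id}_{sess_id}.csv"
                write_pose_csv(track, root / pname)
                session_rows[-1]["pose_file"] = pname

    sessions = pd.DataFrame(
        session_rows,
        columns=[
            "subject_id", "session_id", "phase", "fr", "condition",
            "events_file", "pose_file", "true_rewards", "true_active",
            "true_inactive", "true_latency_s",
        ],
    )
    sessions.to_csv(root / "sessions.csv", index=False)
    pd.DataFrame(
        truth_bin_rows, columns=["subject_id", "session_id", "fr", "true_rewards"]
    ).to_csv(root / "truth_bins.csv", index=False)
    pd.DataFrame(
        oestrus_rows, columns=["subject_id", "session_id", "phase_label"]
    ).to_csv(root / "oestrus.csv", index=False)

    manifest = {
        "seed": int(seed),
        "n_subjects": len(experimental),
        "phases": list(config.phases),
        "n_sessions": len(sessions),
        "files": {
            "designs": "designs.csv",
            "sessions": "sessions.csv",
            "truth_bins": "truth_bins.csv",
            "oestrus": "oestrus.csv",
            "ground_truth": "ground_truth.json" if truth else None,
            "landmarks": "landmarks.json" if config.pose_for else None,
        },
    }
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=1), encoding="utf-8"
    )
    return CohortBundle(
        root=root, designs=design_df, sessions=sessions, truth=truth,
        manifest=manifest,
    )
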