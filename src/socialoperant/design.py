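"""Subject design tables: sex, housing, time-of-day, role, chamber.

The study design is a fully crossed Sex (F/M) x Housing (isolated/paired)
x Time-of-day (light/dark) between-subjects layout with experimental
subjects balanced across operant chambers. Chamber assignment keeps the
sex of experimental rats consistent within a chamber, which is what makes
the "top 50% per Sex x Housing x ToD x chamber" selection rule well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import product

import pandas as pd

__all__ = ["SubjectDesign", "factorial_design", "designs_to_frame", "frame_to_designs"]

SEXES = ("F", "M")
HOUSINGS = ("isolated", "paired")
TODS = ("light", "dark")
ROLES = ("experimental", "stimulus")


@dataclass(frozen=True)
class SubjectDesign:
    """One subject's assignment to the between-subjects factors."""

    subject_id: str
    sex: str
    housing: str
    tod: str
    role: str = "experimental"
    chamber_id: str = "ch0"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.housing not in HOUSINGS:
            raise ValueError(f"unknown housing {self.housing!r}")
        if self.tod not in TODS:
            raise ValueError(f"unknown time-of-day {self.tod!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


def factorial_design(
    n_per_cell: int = 8, chambers_per_cell: int = 2
) -> list[SubjectDesign]:
    """Balanced Sex x Housing x ToD design with chamber assignment.

    Parameters
    ----------
    n_per_cell
        Experimental subjects per factorial cell (8 in the full study,
        giving N = 64).
    chambers_per_cell
        Number of operant chambers each cell's subjects are split
        across; subjects are assigned round-robin so chamber sub-cells
        are as even as possible.
    """
    if n_per_cell < 0 or chambers_per_cell < 1:
        raise ValueError("invalid design sizes")
    designs: list[SubjectDesign] = []
    idx = 0
    for sex, housing, tod in product(SEXES, HOUSINGS, TODS):
        for i in range(n_per_cell):
            chamber = f"{sex}{housing[0]}{tod[0]}-c{i % chambers_per_cell}"
            designs.append(
                SubjectDesign(
                    subject_id=f"s{idx:03d}",
                    sex=sex,
                    housing=housing,
                    tod=tod,
                    chamber_id=chamber,
                )
            )
            idx += 1
    return designs


def designs_to_frame(designs: list[SubjectDesign]) -> pd.DataFrame:
    cols = ["subject_id", "sex", "housing", "tod", "role", "chamber_id"]
    if not designs:
        return pd.DataFrame(columns=cols)
    ids = [d.subject_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError("subject_id values must be unique")
    return pd.DataFrame([asdict(d) for d in designs], columns=cols)


def frame_to_designs(df: pd.DataFrame) -> list[SubjectDesign]:
    return [
        SubjectDesign(
            subject_id=str(r.subject_id),
            sex=r.sex,
            housing=r.housing,
            tod=r.tod,
            role=r.role,
            chamber_id=str(r.chamber_id),
        )
        for r in df.itertuples(index=False)
    ]
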