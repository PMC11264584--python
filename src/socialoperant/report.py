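"""Summary tables: group descriptives, demand parameters, correlations.

Produces tidy, documented CSV-ready tables per Sex x Housing (x stimulus
sex) cell — group mean and SEM for each operant outcome, population
demand parameters, and the Q0-alpha correlation table with the Fisher-z
sex comparison. No further inferential statistics are computed here;
the tables are consumable by standard statistics tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import compare_correlations_fisher, pearson_correlation

__all__ = ["group_outcome_summary", "correlation_table"]

OUTCOME_COLS = (
    "rewards",
    "active_minus_inactive",
    "latency_first_active_s",
    "log10_latency",
)


def group_outcome_summary(
    outcomes: pd.DataFrame,
    designs: pd.DataFrame,
    group_cols: tuple[str, ...] = ("sex", "housing"),
    value_cols: tuple[str, ...] = OUTCOME_COLS,
) -> pd.DataFrame:
    """Per-subject means aggregated to cell mean ± SEM.

    Cells with a single subject report a missing SEM with a reason;
    empty cells of the full factorial are reported as missing rows, not
    silently dropped.
    """
    merged = outcomes.merge(designs, on="subject_id", how="left")
    value_cols = [c for c in value_cols if c in merged.columns]
    per_subject = merged.groupby(["subject_id", *group_cols], dropna=False)[
        list(value_cols)
    ].mean().reset_index()
    rows = []
    levels = [sorted(designs[c].dropna().unique()) for c in group_cols]
    keys = pd.MultiIndex.from_product(levels, names=group_cols)
    grouped = per_subject.groupby(list(group_cols))
    for key in keys:
        key = key if isinstance(key, tuple) else (key,)
        try:
            cell = grouped.get_group(key if len(key) > 1 else key[0])
        except KeyError:
            cell = per_subject.iloc[0:0]
        base = dict(zip(group_cols, key))
        n = len(cell)
        for col in value_cols:
            row = dict(base, outcome=col, n=n)
            if n == 0:
                row.update(mean=np.nan, sem=np.nan, missing_reason="empty cell")
            else:
                vals = cell[col].to_numpy(float)
                row["mean"] = float(np.nanmean(vals))
                if n > 1:
                    row["sem"] = float(np.nanstd(vals, ddof=1) / np.sqrt(n))
                    row["missing_reason"] = None
                else:
                    row["sem"] = np.nan
                    row["missing_reason"] = "single subject (SEM undefined)"
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_table(fits: pd.DataFrame, designs: pd.DataFrame) -> pd.DataFrame:
    """Q0 vs log-elasticity correlations: cohort, by sex, and Fisher z.

    Uses non-excluded, fittable subjects with defined log10 alpha.
    Returns rows (scope, r, df, p, n) plus a ``fisher_z`` comparison row
    (z in column r, p two-sided) when both sexes have n >= 4.
    """
    df = fits.merge(designs[["subject_id", "sex"]], on="subject_id", how="left")
    df = df[df["fittable"] & ~df["excluded"]].dropna(subset=["q0", "log10_alpha"])
    rows = []
    by_sex: dict[str, tuple] = {}
    for scope, sub in [("cohort", df), *[(s, g) for s, g in df.groupby("sex")]]:
        if len(sub) < 3:
            rows.append(
                {"scope": scope, "r": np.nan, "df": np.nan, "p": np.nan,
                 "n": len(sub), "note": "fewer than 3 subjects"}
            )
            continue
        res = pearson_correlation(sub["q0"], sub["log10_alpha"])
        rows.append(
            {"scope": scope, "r": res.r, "df": res.df, "p": res.p,
             "n": res.n, "note": None}
        )
        if scope != "cohort":
            by_sex[scope] = (res.r, res.n)
    if len(by_sex) == 2 and all(n >= 4 for _, n in by_sex.values()):
        (r1, n1), (r2, n2) = (by_sex[s] for s in sorted(by_sex))
        z, p = compare_correlations_fisher(r1, n1, r2, n2)
        rows.append(
            {"scope": "fisher_z(" + " vs ".join(sorted(by_sex)) + ")",
             "r": z, "df": np.nan, "p": p, "n": n1 + n2, "note": "z statistic"}
        )
    return pd.DataFrame(rows)
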