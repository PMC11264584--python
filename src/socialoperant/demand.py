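"""Exponential demand-curve economics for social reward.

Consumption Q (social rewards) at behavioural price C (lever presses per
reward, the FR value) is modelled with the exponential demand equation

    log10 Q = log10 Q0 + k * (exp(-alpha * Q0 * C) - 1)

where Q0 is demand at null cost (the hedonic set-point: consumption the
subject would take at zero price), alpha is demand elasticity (the rate
at which consumption decays as price rises; lower alpha = more
persistent demand = higher motivation) and k is a span constant fixing
the log10 range of consumption the curve can traverse.

Fitting is least squares on the log10 scale, with R-squared computed on
the same scale; subjects whose best fit has R-squared below 0.6 are
flagged excluded. Elasticity is log10-transformed for downstream group
analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DemandFit",
    "predict_consumption",
    "shared_k",
    "fit_demand_curve",
    "fit_cohort",
    "population_demand_curve",
    "between_session_consumption",
    "within_session_consumption",
    "R2_EXCLUSION_DEFAULT",
]

R2_EXCLUSION_DEFAULT = 0.6


def predict_consumption(q0, alpha, k, price_c):
    """Predicted consumption Q at price C under the exponential model.

    Vectorised over ``price_c``. ``Q(0) == q0`` exactly, and Q is
    non-increasing in C (strictly decreasing when alpha > 0).
    """
    q0 = float(q0)
    alpha = float(alpha)
    k = float(k)
    if q0 <= 0:
        raise ValueError("q0 must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    c = np.asarray(price_c, dtype=float)
    if np.any(c < 0):
        raise ValueError("price must be non-negative")
    out = q0 * 10.0 ** (k * (np.exp(-alpha * q0 * c) - 1.0))
    return out if out.ndim else float(out)


def shared_k(consumption) -> float:
    """Cohort-level span constant.

    log10(max mean consumption) - log10(min positive mean consumption)
    + 0.5, the convention that keeps alpha comparable across subjects
    fitted with a common k.
    """
    q = np.asarray(consumption, dtype=float)
    q = q[np.isfinite(q) & (q > 0)]
    if q.size == 0:
        raise ValueError("no positive consumption values for k")
    return float(np.log10(q.max()) - np.log10(q.min()) + 0.5)


@dataclass
class DemandFit:
    """Per-subject exponential demand parameters and fit diagnostics."""

    subject_id: str
    q0: float
    alpha: float
    k: float
    r_squared: float
    n_points_used: int
    excluded: bool
    fittable: bool = True
    condition: str | None = None

    @property
    def log10_alpha(self) -> float:
        """log10 elasticity; NaN when alpha is zero or the fit failed."""
        if not self.fittable or not self.alpha > 0:
            return float("nan")
        return float(np.log10(self.alpha))

    def predict(self, price_c):
        return predict_consumption(self.q0, self.alpha, self.k, price_c)


def _unfittable(subject_id: str, k: float, n: int, condition=None) -> DemandFit:
    return DemandFit(
        subject_id=subject_id,
        q0=float("nan"),
        alpha=float("nan"),
        k=k,
        r_squared=float("nan"),
        n_points_used=n,
        excluded=True,
        fittable=False,
        condition=condition,
    )


def fit_demand_curve(
    prices,
    consumption,
    k: float,
    *,
    subject_id: str = "",
    condition: str | None = None,
    r2_threshold: float = R2_EXCLUSION_DEFAULT,
    zero_policy: str = "drop",
    zero_floor: float = 0.1,
) -> DemandFit:
    """Fit the exponential demand equation to one subject's data.

    Least squares on log10 Q with a multi-start over the elasticity
    axis (the objective is multimodal in alpha); Q0 is optimised on the
    log10 scale. Zero-consumption price points are dropped by default
    (``zero_policy="floor"`` substitutes ``zero_floor`` instead). Fewer
    than three positive points yields an unfittable result.
    """
    if zero_policy not in ("drop", "floor"):
        raise ValueError("zero_policy must be 'drop' or 'floor'")
    c = np.asarray(prices, dtype=float)
    q = np.asarray(consumption, dtype=float)
    if c.shape != q.shape:
        raise ValueError("prices and consumption must align")
    if np.any(c <= 0):
        raise ValueError("fitted prices must be positive (C=0 is extrapolation)")
    ok = np.isfinite(q)
    if zero_policy == "floor":
        q = np.where(ok & (q <= 0), zero_floor, q)
    keep = ok & (q > 0)
    if (~keep & ok).any():
        logger.info(
            "subject %s: dropping %d zero-consumption price point(s)",
            subject_id,
            int((~keep & ok).sum()),
        )
    c, q = c[keep], q[keep]
    if c.size < 3:
        return _unfittable(subject_id, k, int(c.size), condition)

    y = np.log10(q)
    qmax = q.max()

    def residuals(theta):
        log_q0, alpha = theta
        return log_q0 + k * (np.exp(-alpha * 10.0**log_q0 * c) - 1.0) - y

    # multi-start over elasticity: alpha*q0*cmax spanning ~1e-2..1e1
    scale = 1.0 / (qmax * c.max())
    alpha_starts = [0.0] + [g * scale for g in (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)]
    lo = [np.log10(qmax) - 3.0, 0.0]
    hi = [np.log10(qmax) + 3.0, np.inf]
    best = None
    for a0 in alpha_starts:
        sol = least_squares(
            residuals,
            x0=[np.log10(qmax), a0],
            bounds=(lo, hi),
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None or not best.success:
        logger.warning("subject %s: demand fit did not converge", subject_id)
        return _unfittable(subject_id, k, int(c.size), condition)

    log_q0, alpha = best.x
    if alpha * 10.0**log_q0 * c.max() < 1e-8:
        alpha = 0.0  # numerically indistinguishable from perfect inelasticity
    ss_res = float(np.sum(residuals(best.x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 1e-12:
        r2 = 1.0 - ss_res / ss_tot
    else:  # flat observations: perfect fit iff residuals vanish
        r2 = 1.0 if ss_res < 1e-10 else -np.inf
    return DemandFit(
        subject_id=subject_id,
        q0=float(10.0**log_q0),
        alpha=float(alpha),
        k=k,
        r_squared=r2,
        n_points_used=int(c.size),
        excluded=bool(r2 < r2_threshold),
        condition=condition,
    )


def fit_cohort(
    observations: pd.DataFrame,
    *,
    k_policy: str = "shared",
    k_value: float | None = None,
    r2_threshold: float = R2_EXCLUSION_DEFAULT,
    zero_policy: str = "drop",
) -> pd.DataFrame:
    """Fit every subject (x condition) in a tidy observation table.

    ``observations`` columns: subject_id, price, consumption, and
    optionally condition. ``k_policy`` is "shared" (one cohort-level k
    from :func:`shared_k`), "fixed" (use ``k_value``) or "per_subject".
    Returns a tidy fit table including log10_alpha and exclusion flags.
    """
    if k_policy not in ("shared", "fixed", "per_subject"):
        raise ValueError(f"unknown k_policy {k_policy!r}")
    obs = observations.copy()
    if "condition" not in obs.columns:
        obs["condition"] = None
    k_shared = None
    if k_policy == "shared":
        k_shared = shared_k(obs["consumption"])
    elif k_policy == "fixed":
        if k_value is None:
            raise ValueError("k_policy='fixed' requires k_value")
        k_shared = float(k_value)
    rows = []
    for (sid, cond), grp in obs.groupby(["subject_id", "condition"], dropna=False):
        k = k_shared if k_shared is not None else shared_k(grp["consumption"])
        fit = fit_demand_curve(
            grp["price"],
            grp["consumption"],
            k,
            subject_id=str(sid),
            condition=None if pd.isna(cond) else cond,
            r2_threshold=r2_threshold,
            zero_policy=zero_policy,
        )
        rows.append(
            {
                "subject_id": fit.subject_id,
                "condition": fit.condition,
                "q0": fit.q0,
                "alpha": fit.alpha,
                "log10_alpha": fit.log10_alpha,
                "k": fit.k,
                "r_squared": fit.r_squared,
                "n_points_used": fit.n_points_used,
                "excluded": fit.excluded,
                "fittable": fit.fittable,
            }
        )
    return pd.DataFrame(rows)


def population_demand_curve(
    observations: pd.DataFrame,
    group_cols: list[str],
    *,
    k_policy: str = "shared",
    k_value: float | None = None,
) -> pd.DataFrame:
    """Fit the demand model to group-mean consumption at each price.

    Every group needs at least two subjects. Returns one fit row per
    group (columns ``group_cols`` + fit columns).
    """
    if observations.empty:
        raise ValueError("no observations for population fit")
    k = (
        float(k_value)
        if k_policy == "fixed" and k_value is not None
        else shared_k(observations["consumption"])
    )
    rows = []
    for key, grp in observations.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        if grp["subject_id"].nunique() < 2:
            raise ValueError(f"group {key} has fewer than 2 subjects")
        mean_q = grp.groupby("price")["consumption"].mean()
        fit = fit_demand_curve(
            mean_q.index.to_numpy(),
            mean_q.to_numpy(),
            k,
            subject_id="|".join(map(str, key)),
        )
        row = dict(zip(group_cols, key))
        row.update(
            q0=fit.q0,
            alpha=fit.alpha,
            log10_alpha=fit.log10_alpha,
            k=fit.k,
            r_squared=fit.r_squared,
            n_points_used=fit.n_points_used,
            excluded=fit.excluded,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def between_session_consumption(
    outcomes: pd.DataFrame, fr_levels=None
) -> pd.DataFrame:
    """Between-session consumption: adjusted rewards per price point.

    For each subject and FR level, consumption is the mean over that
    FR's sessions of active presses divided by the FR requirement (the
    "adjusted rewards" measure, continuous-valued). ``outcomes`` needs
    columns subject_id, fr, active_presses.
    """
    req = {"subject_id", "fr", "active_presses"}
    if not req.issubset(outcomes.columns):
        raise ValueError(f"outcomes table needs columns {sorted(req)}")
    df = outcomes.copy()
    df["adjusted"] = df["active_presses"] / df["fr"]
    out = (
        df.groupby(["subject_id", "fr"], as_index=False)["adjusted"]
        .mean()
        .rename(columns={"fr": "price", "adjusted": "consumption"})
    )
    if fr_levels is not None:
        expected = set(int(f) for f in fr_levels)
        for sid, grp in out.groupby("subject_id"):
            missing = expected - set(grp["price"].astype(int))
            if missing:
                warnings.warn(
                    f"subject {sid} missing FR level(s) {sorted(missing)}",
                    stacklevel=2,
                )
    return out.sort_values(["subject_id", "price"], ignore_index=True)


def within_session_consumption(
    bin_rewards: pd.DataFrame, *, expected_sessions: int = 4
) -> pd.DataFrame:
    """Within-session consumption: mean rewards per FR bin per condition.

    ``bin_rewards`` is tidy with columns subject_id, session_id,
    condition (stimulus sex), fr, rewards — one row per FR bin per
    session. Consumption at price C is the mean of the C-bin's reward
    count across the condition's sessions.
    """
    req = {"subject_id", "session_id", "condition", "fr", "rewards"}
    if not req.issubset(bin_rewards.columns):
        raise ValueError(f"bin_rewards table needs columns {sorted(req)}")
    for (sid, cond), grp in bin_rewards.groupby(["subject_id", "condition"]):
        n = grp["session_id"].nunique()
        if n < expected_sessions:
            warnings.warn(
                f"subject {sid} condition {cond}: {n} session(s), "
                f"expected {expected_sessions}",
                stacklevel=2,
            )
    out = (
        bin_rewards.groupby(["subject_id", "condition", "fr"], as_index=False)[
            "rewards"
        ]
        .mean()
        .rename(columns={"fr": "price", "rewards": "consumption"})
    )
    return out.sort_values(["subject_id", "condition", "price"], ignore_index=True)
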