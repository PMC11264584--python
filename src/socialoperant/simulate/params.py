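"""Ground-truth subject parameters and cohort sampling.

Each simulated subject carries true demand parameters (Q0, alpha) from
which the session simulator calibrates its press process, so that every
downstream stage can be checked against known ground truth. Group
structure enters through multiplicative Sex x Housing effects on the
log-normal group means: the default scenario encodes the study's
headline pattern — isolation raises Q0 and lowers alpha (raises
motivation) in females only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..design import SubjectDesign

__all__ = [
    "TrueSubjectParams",
    "EffectScenario",
    "CohortGroundTruth",
    "sample_cohort_params",
    "female_isolation_scenario",
]

CellKey = tuple[str, str]  # (sex, housing)


@dataclass(frozen=True)
class TrueSubjectParams:
    """One subject's generating parameters.

    q0_true is rewards per session (per bin for within-session
    programs) at null cost; alpha_true the demand-elasticity rate;
    press_rate_base the subject's maximum press rate (presses/s);
    inactive_rate a low constant inactive-press rate (presses/s);
    satiety_halflife_s an optional within-session half-life of the
    press rate emulating front-loading; k_true the demand-curve span
    constant used to calibrate the press process.
    """

    subject_id: str
    q0_true: float
    alpha_true: float
    press_rate_base: float = 2.0
    inactive_rate: float = 0.005
    satiety_halflife_s: float | None = None
    k_true: float = 2.0

    def __post_init__(self) -> None:
        if self.q0_true <= 0:
            raise ValueError("q0_true must be positive")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be non-negative")
        if self.press_rate_base < 0 or self.inactive_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class EffectScenario:
    """Group-effect configuration for cohort sampling.

    Baselines are the geometric means of the reference cells;
    multipliers scale them per (sex, housing) cell; sigma_log is the
    between-subject log-normal dispersion (natural-log sd). The Q0
    baseline of 20 rewards/session sits inside the observed range of
    mean rewards per daily run (18.5-24.5) at low price.
    """

    q0_base: float = 20.0
    alpha_base: float = 3e-3
    k: float = 2.0
    sigma_log: float = 0.25
    q0_multipliers: dict[CellKey, float] = field(default_factory=dict)
    alpha_multipliers: dict[CellKey, float] = field(default_factory=dict)
    press_rate_base: float = 2.0
    inactive_rate: float = 0.005
    satiety_halflife_s: float | None = None

    def __post_init__(self) -> None:
        if self.q0_base <= 0 or self.alpha_base < 0 or self.k <= 0:
            raise ValueError("invalid scenario baselines")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")
        for m in (*self.q0_multipliers.values(), *self.alpha_multipliers.values()):
            if m <= 0:
                raise ValueError("effect multipliers must be positive")

    def cell_means(self, sex: str, housing: str) -> tuple[float, float]:
        key = (sex, housing)
        return (
            self.q0_base * self.q0_multipliers.get(key, 1.0),
            self.alpha_base * self.alpha_multipliers.get(key, 1.0),
        )


def female_isolation_scenario(**overrides) -> EffectScenario:
    """Default study scenario: the isolation-induced rise in social
    motivation is specific to females — isolated females get half the
    elasticity and a higher hedonic set-point than every other cell."""
    kwargs = dict(
        q0_multipliers={("F", "isolated"): 1.5},
        alpha_multipliers={("F", "isolated"): 0.5},
    )
    kwargs.update(overrides)
    return EffectScenario(**kwargs)


@dataclass(frozen=True)
class CohortGroundTruth:
    """The simulator's true per-subject parameters plus provenance."""

    params: tuple[TrueSubjectParams, ...]
    scenario: EffectScenario
    rng_seed: int

    def __getitem__(self, subject_id: str) -> TrueSubjectParams:
        for p in self.params:
            if p.subject_id == subject_id:
                return p
        raise KeyError(subject_id)

    def to_dict(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "scenario": {
                **asdict(self.scenario),
                "q0_multipliers": {
                    "|".join(k): v for k, v in self.scenario.q0_multipliers.items()
                },
                "alpha_multipliers": {
                    "|".join(k): v for k, v in self.scenario.alpha_multipliers.items()
                },
            },
            "params": [asdict(p) for p in self.params],
        }


def sample_cohort_params(
    designs: list[SubjectDesign],
    scenario: EffectScenario,
    seed: int,
) -> CohortGroundTruth:
    """Draw per-subject (Q0, alpha) log-normally around the cell means.

    For each experimental subject, parameters are sampled as
    ``mean * exp(N(0, sigma_log))`` so the cell geometric mean equals
    baseline x multiplier exactly in expectation. Deterministic under
    ``seed``; stimulus-role subjects get no parameters.
    """
    if not designs:
        raise ValueError("designs must be non-empty")
    rng = np.random.default_rng(seed)
    params = []
    for d in designs:
        if d.role != "experimental":
            continue
        q0_mean, alpha_mean = scenario.cell_means(d.sex, d.housing)
        q0 = q0_mean * float(np.exp(rng.normal(0.0, scenario.sigma_log)))
        alpha = alpha_mean * float(np.exp(rng.normal(0.0, scenario.sigma_log)))
        params.append(
            TrueSubjectParams(
                subject_id=d.subject_id,
                q0_true=q0,
                alpha_true=alpha,
                press_rate_base=scenario.press_rate_base,
                inactive_rate=scenario.inactive_rate,
                satiety_halflife_s=scenario.satiety_halflife_s,
                k_true=scenario.k,
            )
        )
    return CohortGroundTruth(params=tuple(params), scenario=scenario, rng_seed=seed)


def simulate_demand_observations(
    truth: CohortGroundTruth,
    prices,
    noise_sd_log10: float,
    seed: int,
):
    """Noisy consumption observations straight from the demand model.

    Multiplies each subject's predicted Q(C) by ``10**N(0, sd)`` —
    log10-scale Gaussian noise. This is the fast generative route for
    parameter-recovery studies; the event-level route is
    :func:`socialoperant.simulate.session.simulate_session`.
    Returns a tidy DataFrame (subject_id, price, consumption).
    """
    import pandas as pd

    from ..demand import predict_consumption

    rng = np.random.default_rng(seed)
    prices = np.asarray(prices, dtype=float)
    rows = []
    for p in truth.params:
        q = predict_consumption(p.q0_true, p.alpha_true, p.k_true, prices)
        q = q * 10.0 ** rng.normal(0.0, noise_sd_log10, size=prices.size)
        for c, v in zip(prices, q):
            rows.append({"subject_id": p.subject_id, "price": c, "consumption": v})
    return pd.DataFrame(rows)
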