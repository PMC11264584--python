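"""Correlation statistics: Pearson r and Fisher r-to-z comparison.

The demand analysis relates demand at null cost (Q0) to elasticity
(alpha) across subjects with Pearson correlations, reported with the
r(df) convention df = n - 2, and compares two independent correlations
(e.g. split by sex) with the Fisher z test

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["CorrelationResult", "pearson_correlation", "compare_correlations_fisher"]


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its df = n - 2 and two-sided p."""

    r: float
    n: int
    p: float

    @property
    def df(self) -> int:
        return self.n - 2


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson correlation over complete cases, two-sided p from the
    t transform, df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must align")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), n=n, p=float(res.pvalue))


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's z.

    Returns ``(z, p)`` with a two-sided normal p-value. Requires
    |r| < 1 and n >= 4 in each sample.
    """
    for r in (r1, r2):
        if not -1.0 < r < 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    if n1 < 4 or n2 < 4:
        raise ValueError("each sample needs n >= 4")
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (math.atanh(r1) - math.atanh(r2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return z, float(p)
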