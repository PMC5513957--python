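"""Significance tests on sets of per-subject SNARC slopes.

Within-group detection uses a one-sample t-test of the mean slope against
zero, one-sided in the canonical SNARC direction (mean slope < 0).
Between-group detection uses the Student pooled-variance independent-samples
t-test, two-sided.  Each p-value is then coded 0/1 at one or more alpha
levels with a strict inequality (significant iff p < alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from .errors import DegenerateVarianceError, InvalidParameterError
from .estimation import SlopeSet

__all__ = [
    "DEFAULT_ALPHAS",
    "TestResult",
    "one_sample_snarc_test",
    "two_sample_slope_test",
    "code_significance",
]

DEFAULT_ALPHAS: tuple[float, ...] = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class TestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    sig: Mapping[float, int]


def code_significance(p: float, alpha: float) -> int:
    """1 iff p < alpha (strict, per the 'smaller than alpha' convention)."""
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p must be in [0, 1], got {p}")
    return int(p < alpha)


def one_sample_snarc_test(
    slopes: SlopeSet, alphas: Sequence[float] = DEFAULT_ALPHAS
) -> TestResult:
    """One-sample t-test of the mean slope against 0, one-sided (< 0).

    t = mean / (sd / sqrt(n)) with df = n - 1; the p-value is the lower
    tail because the alternative is the canonical negative SNARC slope.
    """
    if slopes.n < 2:
        raise DegenerateVarianceError("need n >= 2 slopes")
    if slopes.sd_slope == 0.0:
        raise DegenerateVarianceError("all slopes identical: zero variance")
    df = slopes.n - 1
    t = slopes.mean_slope / (slopes.sd_slope / math.sqrt(slopes.n))
    p = float(stats.t.cdf(t, df))
    return TestResult(t, df, p, {a: code_significance(p, a) for a in alphas})


def two_sample_slope_test(
    slopes_a: SlopeSet,
    slopes_b: SlopeSet,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
) -> TestResult:
    """Student pooled-variance independent-samples t-test, two-sided.

    Groups are simulated with equal n and equal trial noise, so the pooled
    form is appropriate (Welch would change df but not the conclusions
    under these conditions).
    """
    na, nb = slopes_a.n, slopes_b.n
    if na < 2 or nb < 2:
        raise DegenerateVarianceError("need n >= 2 slopes in each group")
    va, vb = slopes_a.sd_slope**2, slopes_b.sd_slope**2
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("zero variance in both groups")
    df = na + nb - 2
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / df)
    t = (slopes_a.mean_slope - slopes_b.mean_slope) / (
        pooled * math.sqrt(1.0 / na + 1.0 / nb)
    )
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(t, df, p, {a: code_significance(p, a) for a in alphas})
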