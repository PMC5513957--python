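"""The dRT slope method: per-subject SNARC effect estimation.

For each magnitude the subject's left-hand RTs are averaged and subtracted
from the averaged right-hand RTs, giving the dRT profile.  Regressing dRT
on magnitude by ordinary least squares yields one slope per subject — the
classical single-number measure of that subject's SNARC effect.  The
common baseline cancels in the subtraction, so the slope is exactly
invariant to the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateRegressionError, IncompleteDataError
from .model import LEFT, RIGHT, SubjectTrials

__all__ = ["DRTProfile", "SlopeSet", "drt_profile", "ols_slope", "sample_slopes"]


@dataclass(frozen=True)
class DRTProfile:
    """Mean right-minus-left RT difference (ms) per magnitude."""

    drt: np.ndarray
    magnitudes: tuple[int, ...]

    def __post_init__(self) -> None:
        drt = np.asarray(self.drt, dtype=float)
        if drt.shape != (len(self.magnitudes),):
            raise IncompleteDataError(
                f"profile length {drt.shape} does not match "
                f"{len(self.magnitudes)} magnitudes"
            )
        if not np.all(np.isfinite(drt)):
            raise IncompleteDataError("non-finite dRT values")
        object.__setattr__(self, "drt", drt)
        object.__setattr__(self, "magnitudes", tuple(self.magnitudes))


@dataclass(frozen=True)
class SlopeSet:
    """Per-subject OLS slopes for one simulated sample, with summary stats.

    ``sd_slope`` uses the n-1 denominator, as required by the downstream
    t-tests.
    """

    slopes: np.ndarray
    mean_slope: float
    sd_slope: float
    n: int

    @classmethod
    def from_slopes(cls, slopes: Sequence[float]) -> "SlopeSet":
        arr = np.asarray(slopes, dtype=float)
        if arr.size < 2:
            raise DegenerateRegressionError(
                "need at least 2 subjects to summarise slopes"
            )
        return cls(
            slopes=arr,
            mean_slope=float(arr.mean()),
            sd_slope=float(arr.std(ddof=1)),
            n=int(arr.size),
        )


def drt_profile(trials: SubjectTrials) -> DRTProfile:
    """Average over repetitions within each hand x magnitude cell, then
    subtract left from right."""
    if not np.all(np.isfinite(trials.rt)):
        raise IncompleteDataError("trial table contains non-finite RTs")
    drt = trials.rt[RIGHT].mean(axis=1) - trials.rt[LEFT].mean(axis=1)
    return DRTProfile(drt=drt, magnitudes=trials.magnitudes)


def ols_slope(profile: DRTProfile, magnitudes: Sequence[int] | None = None) -> float:
    """Least-squares slope of dRT on magnitude, in ms per magnitude unit.

    slope = sum((m - mbar) (y - ybar)) / sum((m - mbar)^2); for magnitudes
    0-9 the denominator is 82.5.
    """
    mags = np.asarray(
        profile.magnitudes if magnitudes is None else magnitudes, dtype=float
    )
    y = profile.drt
    if mags.size < 3 or y.size != mags.size:
        raise DegenerateRegressionError(
            f"need >= 3 aligned points, got {mags.size} magnitudes "
            f"and {y.size} dRTs"
        )
    mc = mags - mags.mean()
    sxx = float(mc @ mc)
    if sxx == 0.0:
        raise DegenerateRegressionError("zero variance in magnitudes")
    return float(mc @ (y - y.mean()) / sxx)


def sample_slopes(
    sample: Sequence[SubjectTrials], magnitudes: Sequence[int] | None = None
) -> SlopeSet:
    """One OLS slope per subject, with sample mean and SD across subjects."""
    if len(sample) == 0:
        raise DegenerateRegressionError("empty sample")
    slopes = [ols_slope(drt_profile(t), magnitudes) for t in sample]
    return SlopeSet.from_slopes(slopes)
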