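"""Generative model for bimanual reaction-time experiments.

A simulated subject responds with the left or right hand to each stimulus
magnitude ``m``.  The two hands share a common baseline (intercept) and
receive opposite halves of the spatial-numerical association:

    RT_right = intercept + m * slope / 2 + error
    RT_left  = intercept - m * slope / 2 + error

so that the expected right-minus-left difference at magnitude ``m`` is
``m * slope``.  ``slope`` is the SNARC slope in milliseconds per magnitude
unit; negative values are the canonical effect (small numbers answered
faster with the left hand, large numbers with the right hand).

Trial noise is a shifted lognormal: right-skewed like empirical RT
distributions, recentred to mean 0 and rescaled so its standard deviation
equals the intra-individual variability ``sdr`` exactly.  The log-scale
standard deviation (``sigma_log``, the "logarithmic compression") controls
the skew only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "SimulationParams",
    "SubjectTrials",
    "lognormal_scale",
    "sample_error",
    "generate_subject",
    "generate_sample",
]

#: Default stimulus magnitudes: the digits 0-9 (ten regression points).
DEFAULT_MAGNITUDES: tuple[int, ...] = tuple(range(10))

#: Default baseline RT (ms), identical for both hands. It cancels exactly
#: in the right-minus-left differences, so its value is cosmetic.
DEFAULT_INTERCEPT: float = 500.0

#: Default log-scale SD of the lognormal trial noise.
DEFAULT_SIGMA_LOG: float = 0.5

#: Hand axis layout of trial arrays.
HANDS: tuple[str, str] = ("left", "right")
LEFT, RIGHT = 0, 1


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for one simulated experimental condition.

    Parameters
    ----------
    slope
        True SNARC slope in ms per magnitude unit (negative = canonical).
    n
        Subjects per sample (per group in two-group designs), >= 2.
    k
        Repetitions per magnitude per hand, >= 1.
    sdr
        Intra-individual trial SD in ms ("SD response"), > 0.
    sigma_log
        Log-scale SD of the lognormal noise (skew parameter), > 0.
    magnitudes
        Ordered integer stimulus magnitudes, at least 3 of them.
    intercept
        Baseline RT in ms, common to both hands.
    """

    slope: float
    n: int
    k: int
    sdr: float
    sigma_log: float = DEFAULT_SIGMA_LOG
    magnitudes: tuple[int, ...] = DEFAULT_MAGNITUDES
    intercept: float = DEFAULT_INTERCEPT

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError(f"n must be >= 2, got {self.n}")
        if self.k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {self.k}")
        if not self.sdr > 0:
            raise InvalidParameterError(f"sdr must be > 0, got {self.sdr}")
        if not self.sigma_log > 0:
            raise InvalidParameterError(
                f"sigma_log must be > 0, got {self.sigma_log}"
            )
        if len(self.magnitudes) < 3:
            raise InvalidParameterError(
                f"need at least 3 magnitudes, got {len(self.magnitudes)}"
            )
        object.__setattr__(self, "magnitudes", tuple(self.magnitudes))

    @property
    def magnitude_array(self) -> np.ndarray:
        return np.asarray(self.magnitudes, dtype=float)


@dataclass(frozen=True)
class SubjectTrials:
    """Raw simulated RTs for one subject.

    ``rt`` has shape ``(2, n_magnitudes, k)`` with axis 0 indexed by
    :data:`HANDS` (0 = left, 1 = right).
    """

    rt: np.ndarray
    magnitudes: tuple[int, ...]

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        if rt.ndim != 3 or rt.shape[0] != 2 or rt.shape[1] != len(self.magnitudes):
            raise InvalidParameterError(
                f"rt must have shape (2, {len(self.magnitudes)}, k), got {rt.shape}"
            )
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "magnitudes", tuple(self.magnitudes))

    @property
    def left(self) -> np.ndarray:
        return self.rt[LEFT]

    @property
    def right(self) -> np.ndarray:
        return self.rt[RIGHT]

    @property
    def k(self) -> int:
        return self.rt.shape[2]


def lognormal_scale(sdr: float, sigma_log: float = DEFAULT_SIGMA_LOG) -> float:
    """Scale factor mapping a standard lognormal to trial noise with SD ``sdr``.

    For ``L = exp(sigma_log * Z)`` with standard-normal ``Z``,
    ``Var(L) = exp(2 sigma^2) - exp(sigma^2)``, so dividing the centred
    variate by ``SD(L)`` and multiplying by ``sdr`` yields noise with
    standard deviation exactly ``sdr``.
    """
    if not sdr > 0 or not sigma_log > 0:
        raise InvalidParameterError("sdr and sigma_log must be positive")
    s2 = sigma_log * sigma_log
    return sdr / math.sqrt(math.exp(2.0 * s2) - math.exp(s2))


def sample_error(
    count: int,
    sdr: float,
    sigma_log: float = DEFAULT_SIGMA_LOG,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``count`` i.i.d. trial-noise values.

    The draws are ``s * (L - E[L])`` with ``L`` lognormal, giving mean 0,
    SD exactly ``sdr``, positive skew, and a finite lower bound of
    ``-s * E[L]`` (an RT can never undershoot the deterministic part by
    more than that).
    """
    if count < 1:
        raise InvalidParameterError(f"count must be >= 1, got {count}")
    s = lognormal_scale(sdr, sigma_log)
    if rng is None:
        rng = np.random.default_rng()
    z = rng.standard_normal(count)
    mean_l = math.exp(0.5 * sigma_log * sigma_log)
    return s * (np.exp(sigma_log * z) - mean_l)


def generate_subject(
    params: SimulationParams,
    rng: np.random.Generator,
    error_sampler: Callable[[int], np.ndarray] | None = None,
) -> SubjectTrials:
    """Simulate the full trial table of a single subject.

    Draws ``2 * |magnitudes| * k`` independent noise values (left hand
    first, then right, C order over magnitude x repetition) and adds the
    deterministic hand-specific ramps.  ``error_sampler`` replaces the
    noise source; passing ``lambda c: np.zeros(c)`` yields the noise-free
    expected RTs, which is useful for exact checks.
    """
    m = params.magnitude_array
    n_cells = 2 * m.size * params.k
    if error_sampler is None:
        err = sample_error(n_cells, params.sdr, params.sigma_log, rng)
    else:
        err = np.asarray(error_sampler(n_cells), dtype=float)
    err = err.reshape(2, m.size, params.k)
    half = m * (params.slope / 2.0)
    rt = np.empty_like(err)
    rt[LEFT] = params.intercept - half[:, None] + err[LEFT]
    rt[RIGHT] = params.intercept + half[:, None] + err[RIGHT]
    return SubjectTrials(rt=rt, magnitudes=params.magnitudes)


def generate_sample(
    params: SimulationParams, rng: np.random.Generator
) -> list[SubjectTrials]:
    """Simulate ``params.n`` independent subjects sharing the same true slope.

    The generative model has no between-subject slope variance: all
    heterogeneity in estimated slopes comes from trial noise.
    """
    return [generate_subject(params, rng) for _ in range(params.n)]
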