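"""Between-cells factorial ANOVA on binary significance outcomes.

The power surface is summarised by treating every replication's 0/1
outcome as an observation in a fully crossed between-subjects ANOVA with
the four design factors.  Fitting a linear model to a binary response is
statistically unorthodox (the residual variance p(1-p) varies across
cells), but it is the conventional way this summary is reported and the
balanced design keeps the sums of squares exactly orthogonal.  Partial
eta squared, SS_effect / (SS_effect + SS_residual), measures how much of
the outcome variation each design factor (or interaction) governs.

Because the design is balanced, effects are computed directly from cell
and marginal means (the classical finite-factor decomposition); Type
I/II/III sums of squares all coincide, and the decomposition adds up to
the total sum of squares exactly.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError, UnbalancedDesignError

__all__ = [
    "factorial_anova",
    "partial_eta2",
    "classify_effect",
    "EFFECT_LABELS",
]

#: Conventional partial-eta-squared benchmarks.
EFFECT_LABELS: tuple[str, ...] = ("negligible", "small", "moderate", "large")
_SMALL, _MODERATE, _LARGE = 0.01, 0.06, 0.14


def classify_effect(eta: float) -> str:
    """Label a partial eta squared: <0.01 negligible, [0.01,0.06) small,
    [0.06,0.14) moderate, >=0.14 large."""
    if not 0.0 <= eta <= 1.0:
        raise InvalidParameterError(f"partial eta squared must be in [0,1], got {eta}")
    if eta < _SMALL:
        return "negligible"
    if eta < _MODERATE:
        return "small"
    if eta < _LARGE:
        return "moderate"
    return "large"


def partial_eta2(ss_effect: float, ss_residual: float) -> float:
    """ss_effect / (ss_effect + ss_residual)."""
    if ss_effect < 0 or ss_residual < 0:
        raise InvalidParameterError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_residual == 0:
        raise InvalidParameterError("partial eta squared undefined: both SS zero")
    return ss_effect / (ss_effect + ss_residual)


def factorial_anova(
    long_table: pd.DataFrame,
    factors: Sequence[str] = ("k", "slope_or_sld", "sdR", "n"),
    response: str = "sig_05",
) -> pd.DataFrame:
    """Full factorial between-cells ANOVA of a (binary) response.

    Parameters
    ----------
    long_table
        One row per observation, with one column per factor and a numeric
        response column (normally the 0/1 significance coding at one
        alpha level).
    factors
        Factor column names; main-effect rows appear in this order,
        followed by all 2-way, 3-way, ... interactions and Residuals.
    response
        Response column name.

    Returns
    -------
    DataFrame with columns ``effect, df, SS, MS, F, partial_eta2, label``.
    The design must be balanced (equal replication count >= 2 per cell);
    unbalanced input raises :class:`UnbalancedDesignError`.

    Notes
    -----
    Effects are estimated by the inclusion-exclusion decomposition of the
    cell-mean array: the term for a factor subset S is its S-marginal
    mean minus all lower-order terms, and its SS is the replication count
    times the squared term summed over the full grid.  In a balanced
    design these SS are exactly orthogonal and sum (with the residual) to
    the total SS.
    """
    factors = list(factors)
    missing = [c for c in [*factors, response] if c not in long_table.columns]
    if missing:
        raise InvalidParameterError(f"missing columns: {missing}")
    if len(factors) < 1:
        raise InvalidParameterError("need at least one factor")

    grouped = long_table.groupby(factors, sort=True, observed=True)[response]
    counts = grouped.size()
    levels = [np.asarray(sorted(long_table[f].unique())) for f in factors]
    shape = tuple(len(l) for l in levels)
    n_cells = int(np.prod(shape))
    if len(counts) != n_cells:
        raise UnbalancedDesignError(
            f"{len(counts)} non-empty cells, expected {n_cells} (empty cells)"
        )
    reps = int(counts.iloc[0])
    if not (counts == reps).all():
        raise UnbalancedDesignError("unequal replication counts across cells")
    if reps < 2:
        raise UnbalancedDesignError("need >= 2 replications per cell")

    # groupby(sort=True) orders cells lexicographically by level, matching
    # a C-order reshape over the sorted level arrays.
    cell_mean = grouped.mean().to_numpy().reshape(shape)
    y = long_table[response].to_numpy(dtype=float)
    grand = cell_mean.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_model = reps * float(((cell_mean - grand) ** 2).sum())
    ss_residual = ss_total - ss_model
    df_residual = y.size - n_cells

    axes = tuple(range(len(factors)))
    terms: dict[frozenset, np.ndarray] = {
        frozenset(): np.full((1,) * len(factors), grand)
    }

    def term(subset: frozenset) -> np.ndarray:
        if subset not in terms:
            marginal = cell_mean.mean(
                axis=tuple(a for a in axes if a not in subset), keepdims=True
            )
            t = marginal.copy()
            for r in range(len(subset)):
                for sub in itertools.combinations(sorted(subset), r):
                    t = t - term(frozenset(sub))
            terms[subset] = t
        return terms[subset]

    rows = []
    ms_residual = ss_residual / df_residual
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(range(len(factors)), order):
            subset = frozenset(combo)
            eff = np.broadcast_to(term(subset), shape)
            ss = reps * float((eff**2).sum())
            df = int(np.prod([shape[a] - 1 for a in combo]))
            if df == 0:  # a constituent factor has a single level
                continue
            ms = ss / df
            f = ms / ms_residual if ms_residual > 0 else np.nan
            if ss == 0.0 and ss_residual == 0.0:
                eta = 0.0
            else:
                eta = partial_eta2(ss, ss_residual)
            rows.append(
                {
                    "effect": ":".join(factors[a] for a in combo),
                    "df": df,
                    "SS": ss,
                    "MS": ms,
                    "F": f,
                    "partial_eta2": eta,
                    "label": classify_effect(eta),
                }
            )
    rows.append(
        {
            "effect": "Residuals",
            "df": df_residual,
            "SS": ss_residual,
            "MS": ms_residual,
            "F": np.nan,
            "partial_eta2": np.nan,
            "label": "",
        }
    )
    return pd.DataFrame(rows)
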