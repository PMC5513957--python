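"""Replicated simulation sweeps over factorial design grids.

Each grid cell fixes one design (slope or slope difference, sample size n,
repetitions k, trial SD).  A cell is replicated many times: every
replication simulates a complete experiment, estimates per-subject slopes,
runs the test, and records 0/1 significance at each alpha.  The proportion
of significant replications is the Monte Carlo power estimate for that
design.

Seeding: a master seed plus the cell's index in the enumerated grid
determine the cell's random stream (``numpy`` ``SeedSequence`` spawn
keys), so any single cell can be re-run in isolation and reproduce its
slice of a full grid run, and cells could be executed in any order or in
parallel without changing results.

The per-cell simulation is vectorised (one big noise array per block of
replications) but draws exactly the same stream, in the same order, as
looping over :func:`snarcpower.model.generate_subject` subject by subject
— an equivalence the test suite asserts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .inference import DEFAULT_ALPHAS
from .model import (
    DEFAULT_INTERCEPT,
    DEFAULT_MAGNITUDES,
    DEFAULT_SIGMA_LOG,
    LEFT,
    RIGHT,
    SimulationParams,
    lognormal_scale,
)

__all__ = [
    "GridSpec",
    "GridCell",
    "CellOutcome",
    "enumerate_grid",
    "cell_seed_sequence",
    "run_cell_one_group",
    "run_cell_two_group",
    "power_estimate",
    "run_grid",
    "alpha_column",
]

Mode = Literal["one_group", "two_group"]

#: Factor levels used for the core 4x4x4x4 power surfaces.
DEFAULT_SLOPES: tuple[float, ...] = (-7.0, -5.0, -3.0, -1.0)
DEFAULT_SLOPE_DIFFS: tuple[float, ...] = (8.0, 6.0, 4.0, 2.0)
DEFAULT_NS: tuple[int, ...] = (10, 20, 30, 40)
DEFAULT_KS: tuple[int, ...] = (10, 20, 30, 40)
DEFAULT_SDRS: tuple[float, ...] = (75.0, 150.0, 225.0, 300.0)

#: Upper bound on elements per noise block; keeps peak memory modest
#: without changing results (the stream order is block-size independent).
_MAX_BLOCK_ELEMS = 20_000_000

# Reusable noise buffer shared across cells.  Large fresh allocations are
# far more expensive than the arithmetic on them, so one workspace is
# grown lazily and reused; grid cells run sequentially (the parallelism
# contract is per-cell seeding with process-level concurrency).
_workspace: np.ndarray | None = None


def _noise_buffer(n_elem: int) -> np.ndarray:
    global _workspace
    if _workspace is None or _workspace.size < n_elem:
        _workspace = np.empty(n_elem, dtype=np.float64)
    return _workspace[:n_elem]


@dataclass(frozen=True)
class GridSpec:
    """Factorial sweep specification.

    ``effects`` holds true slopes (one_group mode) or between-group slope
    differences ``sld`` (two_group mode).  In two-group mode a cell with
    difference ``sld`` simulates groups with slopes
    ``base_slope - sld/2`` and ``base_slope + sld/2``; the two-sample
    test only sees the difference, so ``base_slope`` is cosmetic.
    """

    mode: Mode = "one_group"
    effects: tuple[float, ...] | None = None
    ns: tuple[int, ...] = DEFAULT_NS
    ks: tuple[int, ...] = DEFAULT_KS
    sdrs: tuple[float, ...] = DEFAULT_SDRS
    replications: int = 1000
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    magnitudes: tuple[int, ...] = DEFAULT_MAGNITUDES
    sigma_log: float = DEFAULT_SIGMA_LOG
    intercept: float = DEFAULT_INTERCEPT
    base_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("one_group", "two_group"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.effects is None:
            default = (
                DEFAULT_SLOPES if self.mode == "one_group" else DEFAULT_SLOPE_DIFFS
            )
            object.__setattr__(self, "effects", default)
        for name in ("effects", "ns", "ks", "sdrs", "alphas"):
            if len(getattr(self, name)) == 0:
                raise InvalidParameterError(f"{name} must be non-empty")
        if self.replications < 1:
            raise InvalidParameterError("replications must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.effects) * len(self.ns) * len(self.ks) * len(self.sdrs)


@dataclass(frozen=True)
class GridCell:
    """One design point: its factor levels and position in the grid."""

    index: int
    effect: float  # slope (one_group) or slope difference sld (two_group)
    n: int
    k: int
    sdr: float


@dataclass(frozen=True)
class CellOutcome:
    """Binary significance outcomes of every replication in one cell."""

    cell: GridCell | None
    replications: int
    sig: Mapping[float, np.ndarray]  # alpha -> uint8 vector of length replications

    def __post_init__(self) -> None:
        for a, v in self.sig.items():
            if v.shape != (self.replications,):
                raise InvalidParameterError(
                    f"sig vector for alpha={a} has length {v.shape}, "
                    f"expected {self.replications}"
                )


def enumerate_grid(spec: GridSpec) -> list[GridCell]:
    """Cartesian product of factor levels in effect x n x k x sdr order."""
    return [
        GridCell(index=i, effect=e, n=n, k=k, sdr=s)
        for i, (e, n, k, s) in enumerate(
            itertools.product(spec.effects, spec.ns, spec.ks, spec.sdrs)
        )
    ]


def cell_seed_sequence(master_seed: int, cell_index: int) -> np.random.SeedSequence:
    """Derive the independent random stream of one grid cell.

    The same (master seed, cell index) pair always yields the same stream,
    regardless of which other cells run or in what order.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(cell_index,))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _simulate_slope_matrix(
    params: SimulationParams, replications: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-subject OLS slopes for `replications` independent samples.

    Returns shape (replications, n).  Simulates the full trial tables
    (noise drawn subject by subject in left-then-right, magnitude-major
    order) and applies the dRT regression in closed form.
    """
    mags = params.magnitude_array
    m_sz = mags.size
    mc = mags - mags.mean()
    weights = mc / (mc @ mc)  # dRT @ weights == OLS slope

    s = lognormal_scale(params.sdr, params.sigma_log)
    mean_l = math.exp(0.5 * params.sigma_log**2)
    half = mags * (params.slope / 2.0)

    per_rep = params.n * 2 * m_sz * params.k
    block = max(1, min(replications, _MAX_BLOCK_ELEMS // per_rep))
    out = np.empty((replications, params.n))
    done = 0
    while done < replications:
        r = min(block, replications - done)
        flat = _noise_buffer(r * per_rep)
        rng.standard_normal(out=flat)
        err = flat.reshape(r, params.n, 2, m_sz, params.k)
        # shifted lognormal, in place: s * (exp(sigma * z) - E[exp(sigma * z)])
        err *= params.sigma_log
        np.exp(err, out=err)
        err -= mean_l
        err *= s
        rt_left = err[:, :, LEFT]
        rt_left += params.intercept - half[:, None]
        rt_right = err[:, :, RIGHT]
        rt_right += params.intercept + half[:, None]
        drt = rt_right.mean(axis=3) - rt_left.mean(axis=3)  # (r, n, m)
        out[done : done + r] = drt @ weights
        done += r
    return out


def run_cell_one_group(
    params: SimulationParams,
    replications: int,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    cell: GridCell | None = None,
) -> CellOutcome:
    """Replicate a one-group experiment: one-sample one-sided t vs 0."""
    rng = _as_rng(seed)
    slopes = _simulate_slope_matrix(params, replications, rng)
    mean = slopes.mean(axis=1)
    sd = slopes.std(axis=1, ddof=1)
    df = params.n - 1
    t = mean / (sd / math.sqrt(params.n))
    p = stats.t.cdf(t, df)
    sig = {a: (p < a).astype(np.uint8) for a in alphas}
    return CellOutcome(cell=cell, replications=replications, sig=sig)


def run_cell_two_group(
    params_a: SimulationParams,
    params_b: SimulationParams,
    replications: int,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    cell: GridCell | None = None,
) -> CellOutcome:
    """Replicate a two-group experiment: pooled two-sided t on group slopes.

    Equal group sizes are required; group A's replications are drawn
    first, then group B's, from the same cell stream.
    """
    if params_a.n != params_b.n:
        raise InvalidParameterError("equal group sizes are required")
    rng = _as_rng(seed)
    slopes_a = _simulate_slope_matrix(params_a, replications, rng)
    slopes_b = _simulate_slope_matrix(params_b, replications, rng)
    na = nb = params_a.n
    df = na + nb - 2
    va = slopes_a.var(axis=1, ddof=1)
    vb = slopes_b.var(axis=1, ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / df)
    t = (slopes_a.mean(axis=1) - slopes_b.mean(axis=1)) / (
        pooled * math.sqrt(1.0 / na + 1.0 / nb)
    )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sig = {a: (p < a).astype(np.uint8) for a in alphas}
    return CellOutcome(cell=cell, replications=replications, sig=sig)


def power_estimate(outcome: CellOutcome, alpha: float) -> tuple[float, float]:
    """Power = mean of 0/1 outcomes; MC SE = sqrt(p(1-p)/replications)."""
    v = outcome.sig[alpha]
    p = float(v.mean())
    se = math.sqrt(p * (1.0 - p) / outcome.replications)
    return p, se


def alpha_column(alpha: float) -> str:
    """Column name for an alpha level, e.g. 0.05 -> 'sig_05'."""
    return "sig_" + format(alpha, "g").split(".")[1]


def _run_cell(spec: GridSpec, cell: GridCell) -> CellOutcome:
    seed = cell_seed_sequence(spec.seed, cell.index)
    if spec.mode == "one_group":
        params = SimulationParams(
            slope=cell.effect,
            n=cell.n,
            k=cell.k,
            sdr=cell.sdr,
            sigma_log=spec.sigma_log,
            magnitudes=spec.magnitudes,
            intercept=spec.intercept,
        )
        return run_cell_one_group(
            params, spec.replications, spec.alphas, seed, cell
        )
    common = dict(
        n=cell.n,
        k=cell.k,
        sdr=cell.sdr,
        sigma_log=spec.sigma_log,
        magnitudes=spec.magnitudes,
        intercept=spec.intercept,
    )
    params_a = SimulationParams(slope=spec.base_slope - cell.effect / 2.0, **common)
    params_b = SimulationParams(slope=spec.base_slope + cell.effect / 2.0, **common)
    return run_cell_two_group(
        params_a, params_b, spec.replications, spec.alphas, seed, cell
    )


def run_grid(
    spec: GridSpec, progress: Iterable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute every cell of the grid.

    Returns ``(power_table, outcomes_long)``:

    * ``power_table`` — one row per cell x alpha with columns
      ``mode, slope_or_sld, n, k, sdR, alpha, replications, power, mc_se``.
    * ``outcomes_long`` — one row per cell x replication with the factor
      levels and the 0/1 outcome per alpha (``sig_05, sig_01, ...``);
      this is the input format of the factorial outcome ANOVA.
    """
    cells = enumerate_grid(spec)
    iterator = cells if progress is None else progress(cells)

    power_rows: list[dict] = []
    long_blocks: list[pd.DataFrame] = []
    rep_idx = np.arange(spec.replications)
    for cell in iterator:
        outcome = _run_cell(spec, cell)
        for a in spec.alphas:
            p, se = power_estimate(outcome, a)
            power_rows.append(
                {
                    "mode": spec.mode,
                    "slope_or_sld": cell.effect,
                    "n": cell.n,
                    "k": cell.k,
                    "sdR": cell.sdr,
                    "alpha": a,
                    "replications": spec.replications,
                    "power": p,
                    "mc_se": se,
                }
            )
        block = pd.DataFrame(
            {
                "mode": spec.mode,
                "slope_or_sld": cell.effect,
                "n": cell.n,
                "k": cell.k,
                "sdR": cell.sdr,
                "replication": rep_idx,
            }
        )
        for a in spec.alphas:
            block[alpha_column(a)] = outcome.sig[a]
        long_blocks.append(block)

    power_table = pd.DataFrame(power_rows)
    outcomes_long = pd.concat(long_blocks, ignore_index=True)
    return power_table, outcomes_long
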