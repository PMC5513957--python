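# Methods

## Generative model

A simulated subject performs a bimanual classification task over an
ordered set of integer stimulus magnitudes (default 0–9), responding *k*
times per magnitude with each hand. Trial RTs are

    RT_right(m) = intercept + m * sl / 2 + e
    RT_left(m)  = intercept - m * sl / 2 + e'

with independent noise per trial. Splitting the slope symmetrically over
the two hands makes the expected right-minus-left difference at magnitude
*m* exactly *m*·*sl*. The intercept (default 500 ms) is shared by both
hands and cancels exactly in the dRT subtraction, so its value cannot
affect any downstream statistic; the test suite asserts this invariance.
There is no between-subject slope heterogeneity and no trial-order or
accuracy structure in the model: all variation in estimated slopes comes
from trial noise.

### Trial noise

Empirical RT distributions are right-skewed, so the noise is a shifted
lognormal: with standard-normal *Z* and log-scale SD σ (default 0.5),

    e = s * (exp(sigma * Z) - E[exp(sigma * Z)]),
    s = sdR / sqrt(exp(2 sigma^2) - exp(sigma^2)),

which has mean 0, standard deviation exactly *sdR*, positive skew, and a
finite lower bound −s·exp(σ²/2). σ controls only the shape; *sdR*
(75–300 ms across the default grid) carries all of the noise magnitude.
An alternative reading — putting *sdR* on the log scale — would decouple
the linear-scale noise SD from *sdR* and cannot reproduce the effect-size
structure of the published power surfaces; the linear-scale construction
does, which the acceptance checks confirm.

## Estimation and inference

Per subject, RTs are averaged within each hand × magnitude cell, left is
subtracted from right (dRT), and dRT is regressed on magnitude by OLS.
Slopes are raw (ms per magnitude unit), not standardised; no trimming or
outlier exclusion is applied to simulated trials. Under this model the
per-subject slope has SD

    sd_slope = sqrt(2 * sdR^2 / (k * Sxx)),   Sxx = sum((m - mbar)^2),

(Sxx = 82.5 for magnitudes 0–9), which is the analytic bridge used by the
test suite: Monte Carlo power must agree with the noncentral-t closed
form built from this quantity.

One-group inference is a one-sample t-test of the mean slope against 0,
one-sided in the negative direction (the canonical effect; positive true
slopes are out of scope). Two-group inference is the Student
pooled-variance independent-samples t-test, two-sided, requiring equal
group sizes — under equal n and equal noise Welch's form would differ
only in df. Significance is coded 1 iff p < α (strict), at
α ∈ {0.05, 0.01, 0.001} by default.

## Sweeps, seeding and problem sizes

The default factorial grids cross slope size {−7, −5, −3, −1} ms (or
slope difference {8, 6, 4, 2} ms) × n {10, 20, 30, 40} × k
{10, 20, 30, 40} × sdR {75, 150, 225, 300} ms = 256 cells, each
replicated 1000 times by default. A two-group cell with difference *sld*
simulates groups with slopes ∓*sld*/2; the test only sees the
difference, so the shared baseline slope is configurable but immaterial
(asserted by a location-invariance test). Extended plot grids (k up to
120 in steps of 10; n additionally 12–18 and 50) are expressible through
the same `GridSpec`.

Each cell draws from `SeedSequence(master_seed, spawn_key=(cell_index,))`,
so a master seed fixes every number in every output, cells are
independent, and any cell can be re-run in isolation; cells may be
distributed across processes without changing results. Within a cell the
noise for a block of replications is drawn as one array whose layout
(replication, subject, hand, magnitude, repetition) consumes the stream
in exactly the order of the subject-by-subject generator — the
vectorised kernel and the per-subject API are stream-equivalent, which a
test asserts. The kernel reuses a single preallocated buffer across
cells because large fresh allocations dominate the arithmetic on them.

The acceptance script runs both 256-cell studies at 300 replications per
cell rather than 1000. Partial η² compares between-cell SS to within-cell
binomial SS, and both scale linearly in the replication count, so the
statistic is nearly invariant to it; 300 replications leave its Monte
Carlo noise well under 0.01 while keeping the full run around a minute.

## Outcome ANOVA

The power surface is summarised exactly as it is conventionally
reported: a between-cells factorial ANOVA fitted to the raw 0/1
outcomes, all interactions up to 4-way, F = MS_effect / MS_residual,
partial η² = SS_effect / (SS_effect + SS_residual), labelled negligible
(< 0.01), small (< 0.06), moderate (< 0.14) or large (≥ 0.14). A linear
model on binary responses is heteroscedastic by construction (residual
variance p(1−p) varies across cells); it is retained deliberately for
comparability, not statistical taste — a GLM would be the inferentially
sound choice on real data.

Because the design is balanced, effects are computed from cell-mean
inclusion–exclusion (each term is its marginal mean minus all
lower-order terms) rather than regression contrasts: Type I/II/III SS
coincide, the decomposition sums exactly to the total SS, and the
computation is O(cells) after one pass over the 256 000 rows. Unbalanced
input raises an error rather than silently switching SS types. Factors
with a single level carry zero df and are dropped from the table. The
standalone `partial_eta2` raises when both SS are zero; inside the table
a zero-SS effect reports η² = 0.

## What the simulations do and do not show

The generator reproduces the variance structure that drives power in
this paradigm — trial-level skewed noise propagated through cell means
into slope estimates. It omits features of real data that mainly add
between-subject variance: true slope heterogeneity, speed–accuracy
trade-offs, RT–variability correlations, outlier trimming practices, and
sequential effects. Power estimates here are therefore best-case for a
given (sl, n, k, sdR); on real data the effective between-subject slope
SD is at least the simulated one, and published designs should treat
these curves as upper bounds.

## Numerical notes

- The one-sided p-value is the exact t CDF; cell runners vectorise the
  t statistics over replications.
- The noncentral-t closed form used as a test oracle can underflow to
  NaN at very large noncentrality; the oracle treats NaN as power 1.
- Degenerate inputs (constant slopes, < 3 regression points, zero
  magnitude variance, unequal group sizes) raise typed errors rather
  than propagating NaN.
- Monte Carlo standard error of a power estimate p at R replications is
  sqrt(p(1−p)/R); tolerance in stochastic tests is 3 such SEs (combined
  in quadrature when two estimates are compared).
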