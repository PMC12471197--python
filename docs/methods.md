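# Methods

## Models

**Disc equation.** Consumption of *N* offered prey over exposure time *T*
(days) is modelled as

- Type II: `Na = a'TN / (1 + a'Th N)`
- Type III: `Na = a'TN^2 / (1 + a'Th N^2)`

with instantaneous attack rate `a'` (per day) and handling time `Th` (days
per prey). Both forms share the saturation level `T/Th` (daily maximum
predation rate); `a'/Th` ("theoretical predation") is the conventional
composite index of control potential, and search efficiency is
`S(N) = a'/(1 + a'Th N)`, equal to `a'` at `N = 0` and strictly decreasing
in density.

The plain disc equation assumes prey density is effectively constant over
the exposure window. The bottle design it is applied to does *not* replace
eaten prey, so estimates carry the usual depletion bias; a
Rogers/random-predator correction is deliberately out of scope because the
analysis being reproduced uses the uncorrected equation. Mutual
interference, multi-prey choice and bootstrap intervals on `(a', Th)` are
likewise out of scope.

**Type determination.** The cubic `Na/N = a + bN + cN^2 + dN^3` is fitted
by ordinary least squares on the per-trial consumption ratios and the
response type is called from the sign of `b` alone (`b < 0` → II, `b > 0` →
III, `b == 0` → indeterminate). The standard error of `b` is reported but
never gates the call. A binomial-logit GLM variant
(`fit_polynomial_type(..., method="glm")`) is available for users who prefer
the likelihood-based convention; OLS is the default because the procedure
being reproduced estimates the polynomial by least squares. A fitted `b`
below 1e-10 (relative to the ratio scale) is snapped to exactly zero so
constant-ratio data read as indeterminate rather than inheriting the sign
of floating-point noise.

## Estimation choices

- **Objective.** `fit_holling` minimises the sum of squared residuals on
  consumed counts with `scipy.optimize.least_squares`, both parameters
  bounded below at 1e-6. A solution at the bound (e.g. `Th → 0` on
  non-saturating data) is returned with `converged=False` and a warning —
  never silently.
- **Initialisation.** `a'0` = mean consumption ratio at the lowest density
  divided by `T` (the low-density slope of the response); `Th0` =
  1 / max(consumed) (the saturation reciprocal). Both heuristics sit inside
  the bounds for any non-degenerate data.
- **Fit on raw replicates by default.** `aggregate="mean"` first collapses
  to per-density means; on balanced designs the two give identical
  estimates, and the mean mode reproduces figure-style summaries.
- **R².** Defined as `1 − SSE/SST` about the mean of the observed response
  (consumed counts for the nonlinear fit, ratios for the cubic). For a
  nonlinear model this can in principle be negative; it is a descriptive
  fit-quality number, not an inferential one.
- **Exposure time** defaults to `T = 1.0` day, matching the 24-h trial
  window; every fitting function accepts an override.
- **Ranking.** Predators are ordered by descending `a'/Th`, ties broken by
  `T/Th`, then lexicographically by label, making the order total and
  reproducible.
- **Rounding.** Report layers round half-up (2 decimals, 3 where the
  published tables print 3); internal values keep full precision. The JSON
  report always carries full precision.

## Gut-content summaries

Positive detection rate is `100 * positives / assayed` — computed over
individuals whose DNA was successfully extracted and assayed, not over all
collected individuals; extraction failures are reported separately, and a
taxon with zero assayed individuals has an *undefined* rate (an error on
request, a `None` in summaries), never 0%. The pooled rate over a table is
the detected-count-weighted mean of per-taxon rates, an identity covered by
a property test. Clopper–Pearson intervals use the exact beta-quantile
form, cross-checked in tests against direct binomial tail-sum inversion.
Community composition reports per-species and per-class percentages of the
grand total of collected individuals.

## Synthetic data generator

`simulate_trials` emulates the bottle protocol: densities 5, 10, 15, 20,
25, 30; four replicates per density; one-day exposure. Observed consumption
is a binomial thinning of the offered prey,
`consumed ~ Binomial(N, min(1, mu(N)/N))` with `mu` the disc expectation,
which keeps counts within `[0, N]`; a Poisson layer was rejected because it
can exceed the prey present. `noise="none"` yields the exact real-valued
expectation (so noise-free refitting recovers the generating parameters to
machine precision); `integer_counts=True` rounds those to whole prey for
count-like data. One user seed expands through `SeedSequence` substreams
per density (or per taxon), so extending the design never perturbs draws
in earlier strata.

What the generator does **not** capture, and hence what passing tests do
not show about real bottles: prey depletion within the window (the binomial
rate uses initial density), predator satiation carry-over between
replicates, overdispersion beyond binomial, and any deviation of real
consumption from the disc-equation mean.

**Availability clamp and type calls.** At high attack rates the disc
expectation exceeds the prey offered at low densities (e.g. `mu(5) > 5`
for `a' ≈ 1.3`, `Th ≈ 0.022`). Bottle data are then truncated at
`Na = N`, which flattens the low-density consumption ratios and can flip
the sign of the cubic's linear coefficient — simulated Type II data from
such parameter sets may classify as Type III. `classify_expectation`
therefore applies the cubic procedure directly to the *unclamped* model
expectation ratios, isolating what the classification does to the response
curve itself; stochastic simulate-then-classify behaviour is tested in the
parameter regime where the expectation respects availability. Similarly, a
Type III expectation whose sigmoid rise is complete before the lowest
design density declines over the whole design range and is called II:
type discrimination is a property of the curve *on the sampled densities*,
not of the generating equation label.

## Degenerate inputs and validation

Trials with `consumed > density`, unknown prey stages, or empty files fail
CSV validation with the file and row named. All-zero consumption raises a
no-predation error (the disc equation is unidentifiable); all-zero ratios
raise a degenerate-data error for the cubic; fewer than four distinct
densities make the cubic underdetermined, fewer than three any disc fit.
In the end-to-end report a failing predator × stage group is recorded in
place and the remaining groups complete.

## Known limitations

- Depletion bias (above): `a'` and `Th` estimates from non-replacement
  designs are systematically distorted; the package reproduces that
  convention rather than correcting it.
- With four replicates per density, the sign of the cubic's `b` is a noisy
  classifier; the recovery experiment quantifies this (classification
  frequencies are part of its report).
- The bundled reference estimates are rounded to three decimals as
  published; quantities derived from them can differ in the last printed
  digit from values computed from unrounded estimates.
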