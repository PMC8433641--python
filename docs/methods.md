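# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the design decisions taken where conventions differ
between labs.

## Calibration model

The calibration line is `y = a + b·x` with `y` the integrated peak area
and `x` the nominal concentration (µg/mL). Over a wide range
(0.10–25 µg/mL, more than two decades) chromatographic response noise is
heteroscedastic — the SD of `y` grows roughly in proportion to `x` — so
ordinary least squares, which weights all points equally, lets the top
of the range dominate and degrades accuracy where it matters most, at
the bottom.

**Homoscedasticity test.** Sample variances of the replicate responses
at the lowest and highest levels are compared by `F = s²_high / s²_low`
against the upper F quantile at `1 − α` with `(n_high − 1, n_low − 1)`
degrees of freedom. Default `α = 0.01` (so with triplicates the critical
value is `F(0.99; 2, 2) = 99`). A zero denominator variance is flagged
degenerate rather than raised as a division error. With triplicates the
test has few degrees of freedom, but realistic proportional noise
produces variance ratios of 10⁴–10⁵ between the extreme levels, far
beyond any critical value.

**Weighted fit.** `fit()` minimises `Σ wᵢ (yᵢ − a − b xᵢ)²` with
empirical weights `w = 1`, `1/x` or `1/x²` (weights act on the nominal
concentration; `x = 0` is disallowed — a blank is not a calibration
point). The numerical fit is delegated to statsmodels `WLS`; unit
weights reduce exactly to OLS, and coefficients are invariant under
rescaling all weights by a positive constant. `r²` for weighted fits is
computed on weighted residuals about the weighted mean (statsmodels'
convention), which reduces to the ordinary `r²` at unit weights; the
source conventions for weighted `r²` vary between vendors and this one
is stated explicitly for that reason.

**Weighting selection.** Each candidate scheme is fitted and scored by
`Σ|%RE|`, the sum over calibration points of the absolute
back-calculation relative error `100·(x̂ − x)/x` with
`x̂ = (y − a)/b`. The scheme with the smallest sum wins; ties (which
occur only on effectively noiseless data) break toward the simpler
scheme in the order `1 < 1/x < 1/x²`, with a small relative margin
(10⁻⁹) so floating-point noise cannot promote a more aggressive scheme.

Selection is performed **per replication curve** when emulating a full
validation report (`select_weighting_per_curve`): each replicate
injection series forms its own calibration line with its own slope,
intercept, r² and Σ|%RE|, which is how validation tables present the
analysis. This matters statistically: in Monte-Carlo at the default
design, `1/x²` is correctly chosen for ~97% of single 6-point curves
under proportional noise, but only ~85% of pooled 18-point datasets —
with pooled data the in-sample L1 statistic flips between the two
near-optimal weightings (`1/x`, `1/x²`) more often.

A known limitation of in-sample Σ|%RE| selection, documented here
because a test asserts its consequence: the statistic is structurally
biased toward `1/x²` (whose weighted L2 objective nearly minimises
Σ(%RE)² by construction) *regardless of the true noise shape*, so it
cannot identify homoscedastic data. The workflow retains OLS for
homoscedastic data through the preceding F-test, not through Σ|%RE|.

**Lack-of-fit.** The (weighted) residual sum of squares splits into pure
error `Σ wᵢⱼ (yᵢⱼ − ȳᵢ)²` (within-level, `df = n − L` for `L` levels)
and lack of fit (level means vs the line, `df = L − 2`);
`F = MS_LOF / MS_PE` against the `1 − α` quantile, default `α = 0.05`.
Weights are constant within a level, so the decomposition is exact for
weighted fits too. A numerically exact fit (relative residual below
10⁻¹⁰) reports `F = 0` rather than 0/0.

**Regression ANOVA.** Standard errors come from the weighted
least-squares covariance with `s² = SS_res/(n − 2)`; two-sided t-tests
for slope ≠ 0 and intercept ≠ 0 at 95% confidence; the acceptance logic
expects a significant slope and a non-significant intercept. Noiseless
data are flagged degenerate (slope exactly determined, intercept test
meaningless) instead of reporting zero standard errors silently.

**Back-calculation table.** Per level: mean back-calculated
concentration, %RE of the mean vs nominal, %CV across replicates; the
lowest level carries a ±20% band (LOQ), all others ±15%.

## Sensitivity (LOD/LOQ)

Noise is measured on a blank (diluent) trace, by default peak-to-peak
(`max − min`) with the pharmacopoeial S/N convention `2·signal/h`; an
RMS alternative (sample SD, `S/N = signal/sd`) is available. The
convention is recorded in every result because S/N is meaningless
without it. Acceptance: LOD needs mean S/N ≥ 3 and injection %CV < 15;
LOQ needs mean S/N ≥ 10, every recovery inside 80–110% and %CV < 15.
The mean-S/N reading of the LOQ rule is deliberate: replicate peak-table
S/N values at the quantitation limit commonly straddle 10 (e.g. a 9
among 11s and 14s averaging 12) while the level still quantifies
reliably on average.

## System suitability, robustness, stress

Vendor data systems report tailing and plate count without publishing
formulas, so the USP conventions are adopted: `T = W₀.₀₅/(2f)` and
`N = 5.54 (t_R/w½)²`. When an injection table carries no width columns,
vendor-reported values can be passed through, or the checks are omitted
with a note — never silently failed. Resolution uses baseline widths
(4σ for a Gaussian peak; the measurement helper reads the 13.4%-height
crossing, which equals 4σ exactly for a Gaussian). Forced-degradation
bookkeeping is the plain ratio `100·stressed/control`; values above
100% (area-normalisation drift) are reported as computed, not clamped.

## Kinetics model

Candidate rate laws are linearised — `C` (zero order), `ln C`
(pseudo-first), `1/C` (second) against time — and fitted by OLS; `r²`
is computed on the transformed scale, the scale on which the rate law
is a straight line. The order with the highest mean r² across
replicates wins, ties breaking toward the lower order. Rate-constant
sign conventions: `k = −slope` for zero/first order, `+slope` for
second. Half-lives: `t½ = C₀/2k`, `ln 2/k`, `1/(k C₀)` respectively.

**Replicate aggregation.** Each replicate is fitted on its own; `k` and
`t½` are then averaged across replicates (mean ± sample SD), with `t½`
computed per replicate *before* averaging. By Jensen's inequality
`mean(ln 2/kᵢ) ≥ ln 2/mean(kᵢ)` for positive rates, so the reported
mean half-life sits slightly above `ln 2/k_mean` — e.g. 15.53 h vs
15.40 h for `k = (0.040, 0.045, 0.050)` h⁻¹. This per-replicate
convention is what stability reports that quote `k = 0.045 ± 0.003` h⁻¹
alongside `t½ = 15.67 ± 1.2` h have used, and it is adopted here and
stated prominently because the two conventions differ by more than the
replicate SD.

Concentrations at or below zero (complete degradation) are dropped from
log/reciprocal transforms with a warning rather than imputed; a fit on
fewer than three remaining points fails loudly.

## Synthetic-data generators

The generators emulate the statistical structure the analysis assumes,
not chromatography itself:

* **Noise model**: Gaussian with `sd(y) = sqrt((cv·E[y])² + sd0²)` —
  a proportional part (default cv = 2%, the replicate-precision scale of
  a well-behaved assay) plus an additive floor (default 0). Gaussianity
  is an assumption; no error distribution is identifiable from published
  validation tables. Negative draws are resampled, not clipped, so log
  transforms stay valid.
* **Calibration**: 6 levels (0.10, 1, 3, 8, 15, 25 µg/mL) × 3
  replicates, slope 7000 area/(µg/mL), intercept −60 — the magnitudes of
  the motivating assay. Under these defaults the homoscedasticity test
  rejects at α = 0.01 in ≳95% of seeds.
* **Decay**: C₀ = 5 µg/mL, first order at k = 0.045 h⁻¹ (the acidic
  pH 1.2 condition), 13 equispaced points over 0–24 h, triplicate.
* **Suitability**: five injections, retention-time CV 0.2%, area CV
  0.5%, with a synthetic Gaussian or exponentially-modified-Gaussian
  peak sampled on a fine grid so width-based metrics (w½ = 2.355σ,
  5%-height widths, tailing) have a shape-consistent ground truth.
* **Blank**: zero-mean Gaussian samples.

Determinism: one integer seed drives a named, independent stream per
fixture kind (numpy `default_rng([stream_tag, seed])`), so identical
specs give identical tables and generating one fixture never perturbs
another.

What passing tests on synthetic data do **not** show: real detector
noise is autocorrelated and occasionally non-Gaussian (spikes, drift);
real calibration nonlinearity (detector saturation) is absent by
construction; integration errors and carry-over are not modelled. The
tests demonstrate that the statistical machinery is correct and that the
selection procedures behave as designed under their own assumptions —
not that any particular instrument meets the acceptance limits.

## Problem sizes

Monte-Carlo checks use 100–200 seeds per property (each draw is a small
least-squares problem), which resolves the ≥90%/≥95% selection-rate
assertions with comfortable margin while keeping the full suite in a few
seconds on one CPU.

## Known limitations

* LOD/LOQ from the calibration-curve SD/slope (3.3σ/S, 10σ/S) is not
  implemented; only the S/N approach is.
* No outlier rejection, robust regression, inverse-prediction intervals,
  or quadratic/log-log calibration models.
* No Arrhenius/temperature extrapolation or pH–rate profile modelling;
  kinetics is per-condition.
* Peak integration from raw traces is out of scope: inputs are
  integrated peak tables, and the synthetic peak shapes exist only to
  give the width-based suitability metrics a ground truth.
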