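# Methods

`rookery` packages the time-series diagnostics used for long-run censuses of
seabird breeding colonies — annual aerial counts of occupied nesting
territories at a handful of colonies over ~30 seasons, with occasional gaps
and some colonies counted as sums of named sub-colony partitions. All trend
and regulation analyses operate on log counts; all parameters below are in
log units per year unless stated.

## Data model and imputation

A colony series is (season, count) with seasons labelled by the calendar year
of the ~1 December survey (the 2001/02 austral season is 2001). Where a
colony is the sum of partitions and one partition is uncounted in a season,
the total would be biased toward zero; the missing partition value is imputed
with a **natural cubic smoothing spline** fitted to that partition's own
series. The spline solves the Reinsch/Green–Silverman system
`(I + λK) g = y` directly (dense; series are ≤ ~30 points), with λ chosen by
generalized cross-validation — minimizing `n‖(I−A)y‖²/tr(I−A)²` over a
log-spaced grid with scalar refinement — or fixed by the caller (λ = 0 is the
exact interpolating spline). Choices worth knowing:

* the spline is fitted to **raw counts, not logs**, so imputed values add
  naturally to the observed partitions; results are clamped at 0;
* imputation is refused outside a partition's observed span (interpolation
  only, never extrapolation), and such seasons stay missing in the total;
* observed values are never altered, and imputed seasons are flagged in the
  output so downstream code can exclude them;
* all observed years are fitted jointly (no windowing);
* at least 4 observations are required — below that the penalized system is
  too weakly determined to be trusted for count data.

## Amplitude and growth

* Growth rate: `r_t = ln N_{t+1} − ln N_t`, computed only across consecutive
  census years; transitions broken by a gap or touching a zero count are
  dropped (`r` is scale-free, so units cancel).
* Amplitude index `s`: sample standard deviation (n−1) of **log10** counts.
  Base 10 matters: the calibration "s = 0.35 ⇔ one order of magnitude
  peak-to-trough" is exact in base 10 (a sinusoid spanning one decade has
  log10-SD `1/(2√2) ≈ 0.354`); `r_t` and everything else uses natural logs.
  Both bases are arguments if you need the other convention.

## Density-dependence diagnostics

ACF and PRCF are computed on the **longest contiguous run** of annual
surveys (no imputation inside diagnostics; a diagnostics result from spliced
series would mix autocorrelation with survey design).

* ACF: the denominator-n ("biased") sample autocorrelation of ln counts —
  the convention under which Bartlett's band `±2/√n` is the right yardstick.
  Slow decay to negative values at long lags signals a trend, not a cycle.
* PRCF (partial rate correlation function): at lag d, the partial correlation
  of `r_t` with `ln N` d years back, controlling for the intervening
  abundance lags 1..d−1 only (not intervening rates). Lag 1 is the plain
  Pearson correlation of `r_t` with `ln N` at the transition start —
  significantly negative means direct density dependence. Implemented by
  correlating residuals of least-squares projections on the control lags.
  The band uses n = number of growth rates in the run.
* Phase trajectory: ordered points `(ln N_{t−1}, ln N_t)` plus a signed
  cumulative cross product of successive displacements; negative = clockwise
  orbit in this axis convention, the signature of delayed density dependence.

**Known limitation — PRCF null calibration.** On a driftless random walk the
lag-1 PRCF is biased negative in finite samples (the regressor is the
integrated noise), and at n ≈ 30 Bartlett's band is exceeded in roughly a
quarter of replicates rather than ~5%. When a deterministic trend of the
magnitude seen in real colony records (≥ ~0.02/yr) dominates the walk, the
nominal calibration is restored (≈5% at n = 200). Treat short-series PRCF
flags as anti-conservative; the package's null simulations use the drifting
walk for that reason.

## Change-point trend models

For each colony, ln counts are regressed on years-since-first-season with
**stationary AR(1) errors**: `cov(u_t, u_s) = σ² φ^{|t−s|}/(1−φ²)` evaluated
at the observed years, so survey gaps are handled by powered-up correlation
rather than imputation. Two mean models are fitted:

1. single linear trend (k = 4 parameters: intercept, slope, φ, σ²);
2. piecewise: era-specific intercept and slope split at a fixed breakpoint
   year (default 2001; k = 6). Dummy-variable parameterization — a level
   discontinuity at the breakpoint is allowed, since an abrupt environmental
   event can drop counts in one season.

Estimation is exact Gaussian likelihood with φ profiled out: a 41-point grid
on (−0.98, 0.98) then bounded scalar refinement to 1e-6; β and its standard
errors are GLS at the profiled φ. `σ²` has a floor of 1e-12 so noiseless
fixtures stay finite. Model choice is by AICc
(`−2lnL + 2k + 2k(k+1)/(n−k−1)`), ties to the simpler model; the piecewise
model is only attempted with ≥4 observations per era. The breakpoint is fixed
a priori, not scanned — estimating it would change the selection's sampling
properties entirely.

**ML vs REML.** The default criterion is maximum likelihood, because ML
AICc values are comparable across different mean models. ML, however, biases
φ and σ² downward at n ≈ 30 (simulations at φ = 0.3 estimate φ ≈ 0.19 on
average), so nominal 95% Wald intervals on the slope cover ~89%. For interval
inference `fit_gls_ar1(..., method="reml")` maximizes the restricted
likelihood instead (φ ≈ 0.28 on average in the same simulations; coverage
~91%). Use ML to select, REML to report intervals — the same convention as
mixed-model practice.

The metapopulation growth rate for an era is the mean of `r_t` of the
**summed** member counts (seasons with any member missing are excluded, and
the transitions they break are dropped). Two other definitions were possible
— abundance-weighted mean of colony slopes, or a GLS slope on the summed ln
counts — and would differ at the second decimal; the mean-r definition is
used because it is the direct multi-colony analogue of the per-colony growth
rate.

## Synchrony

Pairwise synchrony is the lag-0 Pearson correlation of two colonies' growth
rates over their **shared observed transitions** (pairs with fewer than 5
shared transitions — configurable — are excluded). Regional synchrony is the
mean of the valid off-diagonal correlations. Because each series is
autocorrelated, the CI for the mean comes from resampling **colonies** with
replacement (1000 replicates by default): each replicate's statistic is the
mean correlation over pairs of distinct resampled colonies, and the interval
is the 2.5/97.5 percentile range. Percentile rather than BCa intervals:
simpler, reproducible, and adequate at these replicate counts. No lagged
cross-correlations are computed.

## Synthetic metapopulation generator

Latent log dynamics per colony i:

    ln N_{i,t+1} = ln N_{i,t} + a(t) + b (ln N_{i,t} − ln K_i)
                   + c_i E_t + ε_{i,t}

with `E_t ~ N(0, σ_env²)` shared across colonies (the Moran effect),
`ε ~ N(0, σ_idio²)` idiosyncratic, and observed counts
`round(N · exp(η))`, `η ~ N(0, σ_obs²)` (multiplicative error — aerial-count
error scales with colony size). Defaults and why:

| parameter | default | rationale |
|---|---|---|
| colonies, seasons | 4, 1981–2012 | the southern-metapopulation design |
| ln K | ln(2825, 43321, 153632, 39391) | colony-size range of the record |
| b | −0.1 | weak regulation: stationary ln-SD ≈ 0.23 puts s in the observed 0.11–0.15 band and lets era drift show in realized trends (time constant 1/\|b\| = 10 yr) |
| era drift a(t) | −0.02 before 2001, +0.07 from 2001 | the two published era growth magnitudes; a transition takes the drift of its starting year |
| c, σ_env, σ_idio | 1, 0.0775, 0.0632 | under b = 0, pairwise growth correlation = c²σ_env²/(c²σ_env²+σ_idio²) = 0.6, the observed synchrony level |
| σ_obs | 0.05 | 5% counting error, a plausible aerial-survey figure |

Missingness masks mimic the survey design rather than missing-at-random:
`southern_annual` keeps all colonies annual except a Beaufort-like island
(17 surveys, longest run 9); `victoria_sparse` gives each colony 3–14
surveys in a short early run plus scattered revisits. Counts are rounded to
positive integers by default; `integer_counts=False` disables rounding for
exactness tests. Everything is deterministic given the seed, and the latent
truth (forcing series, latent ln N, mask) is returned for recovery tests.

What the generator does **not** emulate: age structure and recruitment lags,
dispersal between colonies, observation error correlated across colonies
(same flight, same photo conditions), era-dependent regulation, and
phenology-driven survey-date effects. Passing tests therefore demonstrate
that the estimators recover the statistical structure they target — not that
real colony records satisfy that structure.

The `published_means` fixture is not simulated: it is the published
per-colony summary (mean counts, 2012 counts, s, N, longest run) for 23
western Ross Sea colonies, used as the worked-example input for the
reporting module (grand total 855,625; southern share 28%; largest-colony
share of the southern sum 64%; Bird+Crozier 2012-to-mean ratio 1.8).

## Reporting conventions

Shares are rounded to the nearest whole percent and latest-to-mean ratios to
one decimal, matching how such census headlines are conventionally printed.
The combined (not per-colony) ratio is the headline figure; per-colony ratios
are also emitted.

## Problem sizes in the test suite

Simulation-based tests use 50 replicates for model-selection frequency, 200
for PRCF power/null rates, 500 for interval coverage, and T = 5000 for the
closed-form synchrony recovery — sizes at which the binomial/Monte-Carlo
noise is comfortably inside the asserted bands on a single CPU.
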