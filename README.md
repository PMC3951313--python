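# rookery

Diagnostics for long-term seabird colony census time series — written for
population ecologists monitoring breeding colonies (the motivating case is
~30 years of annual aerial counts of Adélie penguin nesting territories in
the southern Ross Sea, but nothing is species-specific). The package answers
the standard questions such a record poses:

* **How variable is a colony?** The amplitude index *s* — the standard
  deviation of log10 counts, where *s* = 0.35 corresponds to one order of
  magnitude of peak-to-trough variation.
* **Did the trend change?** Generalized least squares on ln counts with
  AR(1) errors, comparing a single linear trend against era-specific trends
  split at a breakpoint year, selected by AICc:
  `ln N_t = β₀ + β₁·t + u_t`, `u_t` AR(1), vs. separate `(β₀, β₁)` per era.
  Slopes are per capita annual growth rates `r = ln N_{t+1} − ln N_t`.
* **Is the colony regulated?** Phase plots of `(ln N_{t−1}, ln N_t)`, the
  ACF of ln counts, and Turchin's partial rate correlation function (PRCF),
  with significance judged against Bartlett's band ±2/√n. A significantly
  negative PRCF at lag 1 indicates direct density dependence.
* **Do colonies move together?** Pairwise cross-correlations of annual
  growth rates, the regional mean, and a bootstrap CI obtained by resampling
  colonies — the Moran-effect question.

Because raw colony censuses are typically available only on request, the
package ships a stochastic Gompertz metapopulation simulator
(`ln N_{t+1} = ln N_t + a(t) + b(ln N_t − ln K) + cE_t + ε`) whose defaults
reproduce the statistical structure of the southern Ross Sea record, so the
whole pipeline is testable end to end. See `docs/methods.md` for the model
details and parameter rationale.

## Worked example

```python
import rookery

colonies, truth = rookery.make_fixture("ross_island", seed=7)

for col in colonies[:2]:
    winner, single, piecewise = rookery.select_trend_model(col, breakpoint_year=2001)
    c, se = winner.coefficients, winner.std_errors
    print(col.colony_id, winner.model_kind,
          f"slopes {c[1]:+.4f} ({se[1]:.4f}) / {c[3]:+.4f} ({se[3]:.4f})")

res = rookery.pairwise_growth_correlations(colonies, min_overlap=5)
res = rookery.mean_synchrony_ci(res, n_boot=1000, seed=1)
print(f"mean synchrony {res.mean_rho:.2f}, CI ({res.ci[0]:.2f}, {res.ci[1]:.2f})")
```

prints

```
Cape Royds piecewise slopes -0.0138 (0.0031) / +0.0574 (0.0063)
Cape Bird piecewise slopes -0.0146 (0.0037) / +0.0534 (0.0078)
mean synchrony 0.29, CI (-0.29, 0.80)
```

— AICc picked the two-trend model for both colonies: a shallow decline
before the 2001 breakpoint, clear growth after (the simulation drifts at
−0.02 then +0.07 per year; regulation damps the realized slopes). The mean
pairwise growth-rate correlation of 0.29 carries a wide colony-bootstrap CI
because only four colonies — one sparsely surveyed — enter the mean.

The `examples/` directory has one narrative script per capability
(`simulate_and_diagnose.py`, `trend_changepoint.py`, `growth_synchrony.py`,
`census_summary.py`); each prints what it computes and what the numbers mean.
A thin CLI mirrors the library for shell use:

```sh
rookery simulate --seed 4 --out census.csv
rookery trend census.csv
rookery diagnose census.csv --plots plots/
rookery synchrony census.csv
rookery summarize census.csv --southern "Cape Royds,Cape Bird,Cape Crozier,Beaufort Island"
```

Input/output is a plain CSV dialect (`colony,region,season,partition,count`)
with smoothing-spline imputation of missing sub-colony partition counts (see
`rookery.interpolate_partition`).

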