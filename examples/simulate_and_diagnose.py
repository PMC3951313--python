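"""Simulate a four-colony metapopulation census and run the regulation
diagnostics: the s amplitude index, ACF, and the partial rate correlation
function (PRCF) with Bartlett's +-2/sqrt(n) band.

A significantly negative PRCF at lag 1 means high counts are followed by low
growth — direct density dependence in the number of pairs returning to breed.
"""

import numpy as np

from rookery import SimConfig, acf, make_fixture, prcf, s_index

colonies, truth = make_fixture("ross_island", seed=7)

print(f"simulated {len(colonies)} colonies, seasons "
      f"{truth.config.seasons[0]}-{truth.config.seasons[1]}, "
      f"density dependence b = {truth.config.b}\n")

for col in colonies:
    run = col.longest_contiguous_run()[0]
    line = f"{col.colony_id:16s} N={col.n_surveys:2d} s={s_index(col):.2f}"
    if run.size >= 15:
        a = acf(col, max_lag=10)
        p = prcf(col, max_lag=10)
        flag = "significant" if p.values[0] < -p.band else "not significant"
        line += (f"  acf(1)={a.values[0]:+.2f}  prcf(1)={p.values[0]:+.2f}"
                 f" (band {p.band:.2f}, {flag})")
    else:
        line += "  (contiguous run too short for lag diagnostics)"
    print(line)

print("\ns ~ 0.1-0.15 means counts vary by a third to half an order of "
      "magnitude; prcf(1) below -band detects the simulated regulation.")
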