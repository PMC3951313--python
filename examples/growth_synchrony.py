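"""Measure spatial synchrony of annual growth rates across colonies.

Pairwise lag-0 correlations of r_t = ln(N_{t+1}) - ln(N_t) restricted to
shared transition years, the regional mean, and a bootstrap CI obtained by
resampling colonies.  The simulator's shared environmental forcing is sized
so the theoretical pairwise correlation is 0.6 (Moran effect).
"""

import numpy as np

from rookery import (
    make_fixture,
    mean_synchrony_ci,
    pairwise_growth_correlations,
)

colonies, truth = make_fixture("ross_island", seed=7)

res = pairwise_growth_correlations(colonies, min_overlap=5)
res = mean_synchrony_ci(res, n_boot=1000, seed=1)

print("pairwise growth-rate correlations (shared transitions in brackets):")
ids = res.colony_ids
for i in range(len(ids)):
    for j in range(i + 1, len(ids)):
        print(f"  {ids[i]:16s} x {ids[j]:16s} rho={res.rho[i, j]:+.2f} "
              f"[{res.n_overlap[i, j]}]")

print(f"\nmean synchrony = {res.mean_rho:.2f}, 95% bootstrap CI "
      f"({res.ci[0]:.2f}, {res.ci[1]:.2f}), {res.n_boot} replicates")
print(f"generating model's theoretical pairwise correlation: "
      f"{truth.config.theoretical_pairwise_rho():.2f} (b = 0 closed form; "
      "regulation and short overlap move the estimate around it).")
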