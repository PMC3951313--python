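"""Spatial synchrony of annual colony growth rates.

Pairwise lag-0 Pearson cross-correlations of growth-rate series restricted to
each pair's shared transition years, the regional mean correlation, and a
bootstrap percentile confidence interval for the mean obtained by resampling
colonies (locations) with replacement — the resampling scheme used for
regional mean synchrony when the series themselves are autocorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diagnostics import growth_rates
from .series import ColonySeries


@dataclass
class SynchronyResult:
    """Pairwise growth-rate correlation structure of a set of colonies.

    ``rho`` is symmetric with unit diagonal; NaN marks pairs excluded for
    insufficient overlap.  ``ci`` is the bootstrap percentile interval for
    ``mean_rho`` (None until :func:`mean_synchrony_ci` fills it).
    """

    colony_ids: list[str]
    rho: np.ndarray
    n_overlap: np.ndarray
    mean_rho: float | None = None
    ci: tuple[float, float] | None = None
    n_boot: int | None = None
    seed: int | None = None

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.colony_ids), k=1)
        vals = self.rho[iu]
        return vals[~np.isnan(vals)]


def pairwise_growth_correlations(
    colonies: list[ColonySeries], min_overlap: int = 5
) -> SynchronyResult:
    """Lag-0 Pearson correlations of r_t between all colony pairs.

    Each pair's correlation uses only the transition years both colonies
    share; pairs sharing fewer than ``min_overlap`` transitions are flagged
    missing (NaN) and excluded from the mean.
    """
    if len(colonies) < 2:
        raise ValueError("need >= 2 colonies")
    ids = [c.colony_id for c in colonies]
    rates = [growth_rates(c).as_dict() for c in colonies]
    m = len(colonies)
    rho = np.eye(m)
    n_overlap = np.zeros((m, m), dtype=int)
    for i in range(m):
        n_overlap[i, i] = len(rates[i])
        for j in range(i + 1, m):
            shared = sorted(set(rates[i]) & set(rates[j]))
            n_overlap[i, j] = n_overlap[j, i] = len(shared)
            if len(shared) < min_overlap:
                rho[i, j] = rho[j, i] = np.nan
                continue
            a = np.array([rates[i][t] for t in shared])
            b = np.array([rates[j][t] for t in shared])
            r = np.corrcoef(a, b)[0, 1]
            rho[i, j] = rho[j, i] = r
    return SynchronyResult(ids, rho, n_overlap)


def mean_synchrony_ci(
    result: SynchronyResult, n_boot: int = 1000, seed: int = 0
) -> SynchronyResult:
    """Regional mean synchrony with a bootstrap percentile interval.

    Colonies are resampled with replacement ``n_boot`` times; each replicate's
    statistic is the mean correlation over pairs of *distinct* resampled
    colonies (self-pairs excluded).  The interval is the 2.5/97.5 percentile
    of the replicate distribution; deterministic given ``seed``.
    """
    m = len(result.colony_ids)
    valid = result.offdiag()
    if m < 3 or valid.size < 3:
        raise ValueError("bootstrap degenerate: need >= 3 colonies with valid pairs")
    mean_rho = float(valid.mean())

    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        vals = []
        for a in range(m):
            for c in range(a + 1, m):
                i, j = idx[a], idx[c]
                if i == j:
                    continue
                v = result.rho[i, j]
                if not np.isnan(v):
                    vals.append(v)
        stats[b] = np.mean(vals) if vals else np.nan
    stats = stats[~np.isnan(stats)]
    lo, hi = np.percentile(stats, [2.5, 97.5])

    return SynchronyResult(
        result.colony_ids, result.rho, result.n_overlap,
        mean_rho=mean_rho, ci=(float(lo), float(hi)),
        n_boot=n_boot, seed=seed,
    )
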