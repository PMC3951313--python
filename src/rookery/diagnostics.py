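"""Per-colony regulation and amplitude diagnostics.

Growth rates r_t = ln(N_{t+1}) - ln(N_t); the s amplitude index (standard
deviation of log10 counts, where s = 0.35 corresponds to one order of
magnitude peak-to-trough variation in a cycling series); sample ACF of
ln-counts; the partial rate correlation function (PRCF) for direct and
delayed density dependence; and phase-plot geometry (ln N_{t-1} vs ln N_t)
with an orbit-orientation statistic.

Correlation significance uses Bartlett's band +-2/sqrt(n).  ACF and PRCF are
computed on the longest contiguous run of annual surveys; no imputation
happens inside diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .series import ColonySeries

logger = logging.getLogger(__name__)


@dataclass
class GrowthRateSeries:
    """Annual per capita growth rates for one colony.

    ``transition_years[i]`` is the year t of the transition t -> t+1 whose
    rate is ``rates[i]``.  Only transitions between consecutive census years
    with positive counts at both ends are present.
    """

    colony_id: str
    transition_years: np.ndarray
    rates: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.transition_years.tolist(), self.rates.tolist()))


@dataclass
class LagDiagnostics:
    """ACF or PRCF values per lag with Bartlett's significance band."""

    kind: str                 # "acf" | "prcf"
    lags: np.ndarray          # 1..L
    values: np.ndarray        # correlations in [-1, 1]
    band: float               # 2/sqrt(n)
    n: int                    # effective series length

    @property
    def significant(self) -> np.ndarray:
        return np.abs(self.values) > self.band


@dataclass
class PhaseTrajectory:
    """Ordered (ln N_{t-1}, ln N_t) points and orbit orientation.

    ``signed_area`` is the cumulative cross product of successive displacement
    vectors in the (x = ln N_{t-1}, y = ln N_t) frame; negative values mean a
    clockwise orbit in that frame, the signature of delayed density-dependent
    feedback.
    """

    colony_id: str
    points: np.ndarray        # shape (m, 2)
    signed_area: float


# ---------------------------------------------------------------------------

def growth_rates(series: ColonySeries) -> GrowthRateSeries:
    """r_t = ln N_{t+1} - ln N_t for every consecutive-year pair.

    Pairs broken by a missing season (gap > 1 year) are omitted; a zero count
    at either end drops that transition with a warning.
    """
    seas, cnt = series.observed()
    if seas.size < 2:
        raise ValueError(f"{series.colony_id}: need >= 2 observed seasons")
    years, rates = [], []
    for i in range(seas.size - 1):
        if seas[i + 1] - seas[i] != 1:
            continue
        if cnt[i] <= 0 or cnt[i + 1] <= 0:
            logger.warning(
                "%s: zero count in transition %d->%d, omitted",
                series.colony_id, seas[i], seas[i + 1],
            )
            continue
        years.append(seas[i])
        rates.append(np.log(cnt[i + 1]) - np.log(cnt[i]))
    return GrowthRateSeries(series.colony_id, np.array(years, dtype=int),
                            np.array(rates, dtype=float))


def s_index(series: ColonySeries, base: float = 10.0) -> float:
    """Amplitude index s: sample SD (n-1 denominator) of log counts.

    Base-10 logs by default, the convention under which s = 0.35 equals one
    order of magnitude of peak-to-trough variation (a sinusoid spanning one
    decade has log10-SD 1/(2*sqrt(2)) ~ 0.354).
    """
    _, cnt = series.observed()
    if cnt.size < 2:
        raise ValueError(f"{series.colony_id}: need >= 2 observed counts")
    if np.any(cnt <= 0):
        raise ValueError(f"{series.colony_id}: s is undefined for non-positive counts")
    return float(np.std(np.log(cnt) / np.log(base), ddof=1))


def acf(series: ColonySeries, max_lag: int) -> LagDiagnostics:
    """Sample autocorrelation of ln-counts at lags 1..max_lag.

    The denominator-n ("biased") estimator over the full-series mean, the
    convention matching Bartlett's band, computed on the longest contiguous
    run of annual surveys.
    """
    seas, cnt = series.longest_contiguous_run()
    n = seas.size
    if n < max_lag + 5:
        raise ValueError(
            f"{series.colony_id}: contiguous run of {n} seasons too short for "
            f"max_lag={max_lag} (need >= {max_lag + 5})"
        )
    y = np.log(cnt)
    if np.ptp(y) == 0:
        raise ValueError(f"{series.colony_id}: degenerate series (zero variance)")
    vals = _sm_acf(y, nlags=max_lag, adjusted=False, fft=False)[1:]
    return LagDiagnostics("acf", np.arange(1, max_lag + 1), vals,
                          band=2.0 / np.sqrt(n), n=n)


def prcf(series: ColonySeries, max_lag: int) -> LagDiagnostics:
    """Partial rate correlation function of Turchin's kind.

    At lag d the PRCF is the partial correlation of the growth rate r_t with
    ln N_{t-d}, controlling for ln N_{t-1}, ..., ln N_{t-(d-1)} (nothing at
    lag 1, where it is the plain Pearson correlation of r_t with ln N_{t-1}).
    A significantly negative value at lag 1 indicates direct density
    dependence; at higher lags, delayed density dependence.

    Implemented by correlating residuals from least-squares projections onto
    the controlled lags.  Band = 2/sqrt(n) with n the number of growth rates.
    """
    seas, cnt = series.longest_contiguous_run()
    rates = np.diff(np.log(cnt))
    n_r = rates.size
    if n_r < max_lag + 5:
        raise ValueError(
            f"{series.colony_id}: {n_r} transitions too few for max_lag={max_lag}"
        )
    lnN = np.log(cnt)
    values = np.empty(max_lag)
    for d in range(1, max_lag + 1):
        # r_t for t = d..n_r-1 (0-based transition index), target ln N_{t-d+1}?
        # transition i is year seas[i] -> seas[i+1]; r_i pairs with ln N at
        # index i (lag 1), i-1 (lag 2), ... i-d+1 (lag d) in lnN.
        idx = np.arange(d - 1, n_r)
        r = rates[idx]
        target = lnN[idx - (d - 1)]
        controls = np.column_stack([lnN[idx - (j - 1)] for j in range(1, d)]) \
            if d > 1 else np.empty((idx.size, 0))
        values[d - 1] = _partial_corr(r, target, controls, lag=d)
    return LagDiagnostics("prcf", np.arange(1, max_lag + 1), values,
                          band=2.0 / np.sqrt(n_r), n=n_r)


def _partial_corr(a: np.ndarray, b: np.ndarray, controls: np.ndarray, lag: int) -> float:
    X = np.column_stack([np.ones(a.size), controls])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient control set at lag {lag}")
    ra = a - X @ np.linalg.lstsq(X, a, rcond=None)[0]
    rb = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        raise ValueError(f"degenerate residuals at lag {lag}")
    return float((ra @ rb) / denom)


def phase_trajectory(series: ColonySeries) -> PhaseTrajectory:
    """Phase-plot points (ln N_{t-1}, ln N_t) plus orbit orientation.

    The signed area is the cumulative cross product of successive displacement
    vectors; a consistently negative value marks clockwise orbits (delayed
    density dependence), zero a degenerate (constant) trajectory.
    """
    seas, cnt = series.observed()
    pts = []
    for i in range(seas.size - 1):
        if seas[i + 1] - seas[i] == 1 and cnt[i] > 0 and cnt[i + 1] > 0:
            pts.append((np.log(cnt[i]), np.log(cnt[i + 1])))
    if len(pts) < 3:
        raise ValueError(f"{series.colony_id}: need >= 3 consecutive-year pairs")
    points = np.array(pts)
    disp = np.diff(points, axis=0)
    cross = disp[:-1, 0] * disp[1:, 1] - disp[:-1, 1] * disp[1:, 0]
    return PhaseTrajectory(series.colony_id, points, float(cross.sum()))
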