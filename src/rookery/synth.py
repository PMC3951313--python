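"""Synthetic metapopulation census generator and canonical fixtures.

The generator produces colony count series with the statistical structure the
analysis modules assume, so every stage is testable without access to the
(request-only) raw survey data:

* lag-1 (Gompertz, log-linear) density dependence with strength ``b``,
* a shared environmental forcing term inducing growth-rate synchrony across
  colonies (the Moran effect),
* piecewise era drift with a breakpoint year (a decline era followed by a
  growth era),
* multiplicative lognormal observation error, and
* survey-design missingness masks that mimic the real monitoring program
  (annual southern surveys with one sparsely counted island; sparse northern
  coast surveys).

Latent dynamics on the log scale:

    ln N_{i,t+1} = ln N_{i,t} + a(t) + b (ln N_{i,t} - ln K_i)
                   + c_i E_t + eps_{i,t}

with E_t ~ N(0, sigma_env^2) shared by all colonies and eps idiosyncratic.
Under b = 0 the pairwise growth-rate correlation has the closed form
c^2 sigma_env^2 / (c^2 sigma_env^2 + sigma_idio^2), which the defaults set
to 0.6 — the level of regional synchrony the analysis is designed to detect.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import ColonySeries

# Colony-size locations (ln scale) resembling the four southern colonies,
# from ~2.8k (Royds-like) to ~150k (Crozier-like) breeding pairs.
_DEFAULT_LOG_K = tuple(np.log([2825.0, 43321.0, 153632.0, 39391.0]))
_SOUTHERN_IDS = ("Cape Royds", "Cape Bird", "Cape Crozier", "Beaufort Island")


@dataclass
class SimConfig:
    """Full parameterization of the stochastic Gompertz metapopulation.

    Defaults are the study conditions of a ~30-season southern-metapopulation
    survey: four colonies spanning 2.8k-150k pairs, weak lag-1 density
    dependence, a shared forcing sized to give pairwise growth-rate
    correlation 0.6, era drift of -0.02/yr before the 2001 breakpoint and
    +0.07/yr from it, and 5% lognormal counting error.  Note that with b < 0
    the realized era slopes are damped below the drift values: the intercept
    drift shifts the Gompertz equilibrium by a/|b| and counts approach it
    with time constant ~1/|b| years.
    """

    n_colonies: int = 4
    seasons: tuple[int, int] = (1981, 2012)
    log_K: tuple[float, ...] = _DEFAULT_LOG_K
    # weak regulation: stationary ln-count SD sqrt((s_env^2+s_idio^2)/(1-(1+b)^2))
    # ~ 0.23, i.e. s ~ 0.10-0.12 in log10 units once era trends are added —
    # the amplitude range of the long-run southern colony record
    b: float = -0.1
    era_drift: tuple[float, float] = (-0.02, 0.07)
    breakpoint_year: int = 2001
    c: tuple[float, ...] | float = 1.0
    sigma_env: float = 0.0775
    sigma_idio: tuple[float, ...] | float = 0.0632
    sigma_obs: float = 0.05
    missing_pattern: str | np.ndarray = "none"   # none | southern_annual | victoria_sparse | bool mask
    integer_counts: bool = True
    colony_ids: tuple[str, ...] | None = None
    region: str = "southern"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasons[1] - self.seasons[0] < 2:
            raise ValueError("seasons must span >= 3 years")
        if len(self.log_K) != self.n_colonies:
            raise ValueError("log_K must have one entry per colony")
        for name in ("sigma_env", "sigma_obs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if np.any(np.asarray(self.sigma_idio_vec) < 0):
            raise ValueError("sigma_idio must be >= 0")
        if self.colony_ids is not None and len(self.colony_ids) != self.n_colonies:
            raise ValueError("colony_ids must have one entry per colony")

    @property
    def year_axis(self) -> np.ndarray:
        return np.arange(self.seasons[0], self.seasons[1] + 1)

    @property
    def c_vec(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.c, dtype=float), (self.n_colonies,))

    @property
    def sigma_idio_vec(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.sigma_idio, dtype=float), (self.n_colonies,)
        )

    def theoretical_pairwise_rho(self) -> float:
        """Closed-form pairwise growth-rate correlation under b = 0.

        Valid for equal loadings and idiosyncratic SDs:
        rho = c^2 s_env^2 / (c^2 s_env^2 + s_idio^2).
        """
        c = float(self.c_vec[0])
        si = float(self.sigma_idio_vec[0])
        num = c * c * self.sigma_env ** 2
        return num / (num + si * si)


@dataclass
class SimTruth:
    """Latent truth returned alongside the observed series, for recovery tests."""

    config: SimConfig
    env: np.ndarray          # E_t per transition, shape (T-1,)
    ln_n: np.ndarray         # latent ln N, shape (n_colonies, T)
    drift: np.ndarray        # a(t) per transition, shape (T-1,)
    mask: np.ndarray = field(default=None)  # observation mask actually applied


def _drift_series(cfg: SimConfig) -> np.ndarray:
    years = cfg.year_axis[:-1]  # transition labelled by its starting year
    a1, a2 = cfg.era_drift
    return np.where(years < cfg.breakpoint_year, a1, a2)


def _build_mask(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    T = cfg.year_axis.size
    if isinstance(cfg.missing_pattern, np.ndarray):
        mask = np.asarray(cfg.missing_pattern, dtype=bool)
        if mask.shape != (cfg.n_colonies, T):
            raise ValueError("explicit mask must be (n_colonies, n_seasons)")
        return mask
    mask = np.ones((cfg.n_colonies, T), dtype=bool)
    if cfg.missing_pattern == "none":
        return mask
    if cfg.missing_pattern == "southern_annual":
        # all colonies annual except the last, surveyed like a sparsely
        # counted offshore island: an early contiguous block then scattered
        # revisits (17 surveys, longest run 9, for a 32-season axis)
        last = cfg.n_colonies - 1
        mask[last] = False
        mask[last, :9] = True
        sparse = np.unique(np.linspace(10, T - 1, 8).round().astype(int))
        mask[last, sparse] = True
        return mask
    if cfg.missing_pattern == "victoria_sparse":
        mask[:] = False
        for i in range(cfg.n_colonies):
            n_obs = int(rng.integers(3, 15))
            run = int(rng.integers(1, min(5, n_obs) + 1))
            # contiguous early run plus scattered later surveys, mimicking
            # near-annual coverage that became infrequent
            start = int(rng.integers(0, max(1, T // 2 - run)))
            mask[i, start:start + run] = True
            remaining = n_obs - run
            pool = np.where(~mask[i])[0]
            if remaining > 0:
                mask[i, rng.choice(pool, size=remaining, replace=False)] = True
        return mask
    raise ValueError(f"unknown missing_pattern {cfg.missing_pattern!r}")


def simulate_metapopulation(
    config: SimConfig,
) -> tuple[list[ColonySeries], SimTruth]:
    """Simulate the metapopulation; fully deterministic given ``config.seed``.

    Returns the observed :class:`ColonySeries` (with the missingness mask
    applied) and a :class:`SimTruth` record carrying all latent quantities.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = cfg.year_axis
    T = years.size
    m = cfg.n_colonies
    logK = np.asarray(cfg.log_K, dtype=float)
    c = cfg.c_vec
    s_idio = cfg.sigma_idio_vec
    drift = _drift_series(cfg)

    env = rng.normal(0.0, cfg.sigma_env, size=T - 1) if cfg.sigma_env > 0 \
        else np.zeros(T - 1)
    eps = rng.normal(0.0, 1.0, size=(m, T - 1)) * s_idio[:, None]

    ln_n = np.empty((m, T))
    ln_n[:, 0] = logK
    for t in range(T - 1):
        ln_n[:, t + 1] = (
            ln_n[:, t] + drift[t] + cfg.b * (ln_n[:, t] - logK)
            + c * env[t] + eps[:, t]
        )

    eta = rng.normal(0.0, cfg.sigma_obs, size=(m, T)) if cfg.sigma_obs > 0 \
        else np.zeros((m, T))
    observed = np.exp(ln_n + eta)
    if cfg.integer_counts:
        observed = np.maximum(np.round(observed), 1.0)

    mask = _build_mask(cfg, rng)
    ids = cfg.colony_ids or tuple(
        _SOUTHERN_IDS[i] if cfg.region == "southern" and i < len(_SOUTHERN_IDS)
        else f"Colony {i + 1}" for i in range(m)
    )
    colonies = [
        ColonySeries(ids[i], cfg.region, years[mask[i]], observed[i, mask[i]])
        for i in range(m)
    ]
    return colonies, SimTruth(cfg, env, ln_n, drift, mask)


def simulate_ar1_trend(
    years: np.ndarray,
    coefficients: np.ndarray,
    phi: float,
    sigma: float,
    rng: np.random.Generator,
    breakpoint_year: int | None = None,
) -> np.ndarray:
    """Generate y = trend + stationary AR(1) noise at the observed years.

    ``coefficients`` is (intercept, slope) for a single trend, or
    (intercept_1, slope_1, intercept_2, slope_2) with ``breakpoint_year`` for
    a piecewise trend, on the years-since-first axis — the exact
    data-generating model of :mod:`rookery.trends`.  Year gaps get
    correlation ``phi**gap`` (the stationary AR(1) at irregular spacing).
    """
    from .trends import _designs  # local import to avoid a cycle at import time

    years = np.asarray(years, dtype=float)
    coefficients = np.asarray(coefficients, dtype=float)
    X_single, X_piece = _designs(
        years, breakpoint_year if breakpoint_year is not None else years[-1] + 1
    )
    X = X_piece if coefficients.size == 4 else X_single
    marg_sd = sigma / np.sqrt(1.0 - phi * phi)
    u = np.empty(years.size)
    u[0] = rng.normal(0.0, marg_sd)
    for i in range(1, years.size):
        gap = years[i] - years[i - 1]
        rho = phi ** gap
        u[i] = rho * u[i - 1] + rng.normal(0.0, marg_sd * np.sqrt(1 - rho * rho))
    return X @ coefficients + u


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

# Published 1981-2012 per-colony census summary for the western Ross Sea:
# mean count of occupied nesting territories, the 2012 count where surveyed,
# the s amplitude index, total surveys N, and the longest contiguous run.
_PUBLISHED_MEANS_CSV = """\
colony,region,mean_count,count_2012,s,n_surveys,n_contiguous
Cape Royds,southern,2825,3083,0.11,30,30
Cape Bird,southern,43321,75696,0.13,30,30
Cape Crozier,southern,153632,272340,0.15,28,28
Beaufort Island,southern,39391,,0.13,17,9
Franklin Island West,victoria_land,60540,,0.11,7,2
Franklin Island East,victoria_land,1110,,0.12,8,2
Inexpressible Island,victoria_land,24450,,0.09,9,2
Terra Nova Bay,victoria_land,11234,,0.13,9,2
Wood Bay,victoria_land,1890,,0.13,8,2
Cape Anne,victoria_land,268,,0.22,6,1
Coulman Island South,victoria_land,17991,,0.09,6,4
Coulman Island Middle,victoria_land,4325,,0.11,9,5
Coulman Island North,victoria_land,1694,,0.10,8,4
Cape Jones,victoria_land,153,,0.14,6,2
Mandible Cirque,victoria_land,16837,,0.10,3,2
Cape Phillips,victoria_land,3921,,0.08,4,3
Cape Wheatstone,victoria_land,2746,,0.18,6,3
Cape Cotter,victoria_land,38252,,0.16,8,3
Cape Hallett,victoria_land,42628,,0.14,14,8
Foyn Island,victoria_land,30494,,0.12,6,1
Possession Island,victoria_land,111306,,0.15,3,1
Downshire Cliffs,victoria_land,19617,,0.12,5,2
Cape Adare,victoria_land,227000,,0.09,4,1
"""

SOUTHERN_COLONIES = list(_SOUTHERN_IDS)

# seasons withheld from each annually surveyed colony in the ross_island
# fixture, matching the published survey totals (N = 30, 30, 28)
_ROSS_ISLAND_MISSING = {
    "Cape Royds": (1983, 2005),
    "Cape Bird": (1986, 2009),
    "Cape Crozier": (1984, 1991, 2003, 2010),
    "Beaufort Island": (),
}


def make_fixture(profile: str, seed: int = 0):
    """Canonical test datasets.

    ``"ross_island"``: four simulated southern colonies, 1981-2012, annual
    surveys with a few withheld seasons plus a sparsely surveyed island
    (17 surveys, 9 contiguous) — survey design matching the published record.

    ``"victoria_land"``: ~20 simulated sparsely surveyed northern colonies
    (3-14 surveys each).

    ``"published_means"``: the published per-colony summary statistics
    (means, 2012 counts, s, N, longest run) as a DataFrame — the in-print
    worked-example input for the reporting module.
    """
    if profile == "published_means":
        df = pd.read_csv(_io.StringIO(_PUBLISHED_MEANS_CSV))
        return df
    if profile == "ross_island":
        cfg = SimConfig(missing_pattern="southern_annual", seed=seed)
        colonies, truth = simulate_metapopulation(cfg)
        out = []
        for col in colonies:
            drop = _ROSS_ISLAND_MISSING.get(col.colony_id, ())
            keep = ~np.isin(col.seasons, drop)
            out.append(ColonySeries(col.colony_id, col.region,
                                    col.seasons[keep], col.counts[keep]))
        return out, truth
    if profile == "victoria_land":
        n = 20
        rng = np.random.default_rng(seed)
        logK = rng.uniform(np.log(150.0), np.log(230000.0), size=n)
        cfg = SimConfig(
            n_colonies=n, log_K=tuple(logK),
            missing_pattern="victoria_sparse",
            colony_ids=tuple(f"Northern {i + 1}" for i in range(n)),
            region="victoria_land", seed=seed + 1,
        )
        return simulate_metapopulation(cfg)
    raise ValueError(f"unknown fixture profile {profile!r}")
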