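"""Read/write colony census CSV and impute missing partition counts.

Canonical dialect: UTF-8 CSV with header ``colony,region,season,partition,count``.
The ``partition`` field is empty for unpartitioned colonies; an empty
``count`` field records a season that was surveyed for the colony but whose
count (or partition count) is missing.

Missing partition counts interior to a partition's observed span are imputed
with a natural cubic smoothing spline fitted to the partition's own series
(smoothing chosen by generalized cross-validation by default), so that colony
totals are not biased toward zero by a single uncounted sub-colony.
Imputation never extrapolates beyond a partition's first/last observed season
and never alters an observed value.
"""

from __future__ import annotations

import csv
import io as _io
from typing import Callable, Iterable, TextIO

import numpy as np
from scipy import optimize

from .series import ColonySeries

HEADER = ["colony", "region", "season", "partition", "count"]


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def read_colony_counts(source: TextIO | str) -> list[ColonySeries]:
    """Parse the canonical census CSV into one :class:`ColonySeries` per colony.

    Parameters
    ----------
    source
        Open text stream, or a path to a CSV file.

    Raises
    ------
    ValueError
        On a duplicated (colony, season, partition) key, a negative or
        non-numeric count (with the offending line number), or a colony mixing
        partitioned and unpartitioned rows.
    """
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_colony_counts(fh)

    reader = csv.DictReader(source)
    missing_cols = set(HEADER) - set(reader.fieldnames or [])
    if missing_cols:
        raise ValueError(f"missing required columns: {sorted(missing_cols)}")

    rows: dict[str, dict] = {}  # colony -> {"region", "cells": {(season, part): count}}
    seen: set[tuple[str, int, str]] = set()
    for lineno, row in enumerate(reader, start=2):
        colony = row["colony"].strip()
        part = (row["partition"] or "").strip()
        try:
            season = int(row["season"])
        except (TypeError, ValueError):
            raise ValueError(f"line {lineno}: non-integer season {row['season']!r}")
        key = (colony, season, part)
        if key in seen:
            raise ValueError(
                f"duplicate row for {colony}/{season}"
                + (f"/{part}" if part else "")
            )
        seen.add(key)
        raw = (row["count"] or "").strip()
        if raw == "":
            count = np.nan
        else:
            try:
                count = float(raw)
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric count {raw!r}")
            if count < 0:
                raise ValueError(f"line {lineno}: negative count {raw!r}")
        entry = rows.setdefault(colony, {"region": row["region"].strip(), "cells": {}})
        entry["cells"][(season, part)] = count

    out = []
    for colony, entry in rows.items():
        cells = entry["cells"]
        parts = sorted({p for (_, p) in cells})
        seasons = np.array(sorted({s for (s, _) in cells}), dtype=int)
        if parts == [""]:
            counts = np.array([cells[(s, "")] for s in seasons])
            out.append(ColonySeries(colony, entry["region"], seasons, counts))
        else:
            if "" in parts:
                raise ValueError(
                    f"{colony}: mixes partition rows with unpartitioned rows"
                )
            partitions = {
                p: np.array([cells.get((s, p), np.nan) for s in seasons])
                for p in parts
            }
            stacked = np.vstack(list(partitions.values()))
            totals = np.where(
                np.isnan(stacked).any(axis=0), np.nan, stacked.sum(axis=0)
            )
            out.append(
                ColonySeries(colony, entry["region"], seasons, totals,
                             partitions=partitions)
            )
    return out


def write_colony_counts(colonies: Iterable[ColonySeries], dest: TextIO | str) -> None:
    """Write colonies in the identical dialect :func:`read_colony_counts` reads.

    Integral counts are written as integers; missing counts as empty fields.
    """
    if isinstance(dest, str):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_colony_counts(colonies, fh)
        return

    writer = csv.writer(dest)
    writer.writerow(HEADER)
    for col in colonies:
        if col.partitions:
            for part, vals in col.partitions.items():
                for s, v in zip(col.seasons, vals):
                    writer.writerow([col.colony_id, col.region, s, part, _fmt(v)])
        else:
            for s, v in zip(col.seasons, col.counts):
                writer.writerow([col.colony_id, col.region, s, "", _fmt(v)])


def _fmt(v: float) -> str:
    if np.isnan(v):
        return ""
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def to_csv_string(colonies: Iterable[ColonySeries]) -> str:
    buf = _io.StringIO()
    write_colony_counts(colonies, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Smoothing-spline imputation
# ---------------------------------------------------------------------------

def fit_smoothing_spline(
    x: np.ndarray, y: np.ndarray, lam: float | None = None
) -> Callable[[np.ndarray], np.ndarray]:
    """Natural cubic smoothing spline minimizing RSS + lam * int f''(t)^2 dt.

    Solves the Reinsch/Green-Silverman system (I + lam K) g = y for the fitted
    values at the knots, with K = Q R^{-1} Q^T built from the knot spacings;
    off-knot evaluation uses the natural-spline piecewise-cubic form.  With
    ``lam=None`` the penalty is chosen by generalized cross-validation,
    minimizing n * ||(I-A)y||^2 / tr(I-A)^2 over a log-spaced grid with
    scalar refinement; ``lam=0`` is the exact interpolating natural spline.

    Works from four points up (census partitions can be that short).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")

    h = np.diff(x)
    Q = np.zeros((n, n - 2))
    R = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        Q[j - 1, j - 1] = 1.0 / h[j - 1]
        Q[j, j - 1] = -1.0 / h[j - 1] - 1.0 / h[j]
        Q[j + 1, j - 1] = 1.0 / h[j]
        R[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            R[j - 1, j] = R[j, j - 1] = h[j] / 6.0
    K = Q @ np.linalg.solve(R, Q.T)

    def gcv(log_lam: float) -> float:
        A = np.linalg.inv(np.eye(n) + 10.0 ** log_lam * K)
        resid = y - A @ y
        denom = (n - np.trace(A)) ** 2
        return n * float(resid @ resid) / denom if denom > 0 else np.inf

    if lam is None:
        grid = np.linspace(-8.0, 8.0, 65)
        scores = [gcv(g) for g in grid]
        i = int(np.argmin(scores))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(gcv, bounds=(lo, hi), method="bounded")
        lam = 10.0 ** float(res.x) if res.fun <= scores[i] else 10.0 ** grid[i]

    g = np.linalg.solve(np.eye(n) + lam * K, y)
    gamma = np.concatenate([[0.0], np.linalg.solve(R, Q.T @ g), [0.0]])

    def evaluate(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        i = np.clip(np.searchsorted(x, t) - 1, 0, n - 2)
        hi_ = h[i]
        a, b = x[i + 1] - t, t - x[i]
        return (a * g[i] + b * g[i + 1]) / hi_ - a * b / 6.0 * (
            (1 + b / hi_) * gamma[i + 1] + (1 + a / hi_) * gamma[i]
        )

    return evaluate


def interpolate_partition(
    seasons: np.ndarray,
    counts: np.ndarray,
    lambda_rule: str | float = "gcv",
    on_edge_gap: str = "raise",
) -> tuple[np.ndarray, set[int]]:
    """Fill interior gaps in a partition series with a cubic smoothing spline.

    A natural cubic smoothing spline is fitted to the observed (season, count)
    pairs, with the penalty weight chosen by generalized cross-validation
    (``lambda_rule="gcv"``, the default) or fixed at a numeric value
    (``0.0`` gives the exact interpolating spline).  Imputed values are the
    spline evaluated at the missing interior seasons, clamped at zero.
    Observed values are never altered.

    Parameters
    ----------
    seasons, counts
        Aligned arrays; NaN in ``counts`` marks a missing season.
    on_edge_gap
        ``"raise"`` refuses any gap at or beyond the first/last observed
        season (no extrapolation); ``"skip"`` leaves such seasons missing.

    Returns
    -------
    (filled_counts, imputed_seasons)
    """
    seasons = np.asarray(seasons, dtype=float)
    counts = np.asarray(counts, dtype=float)
    obs = ~np.isnan(counts)
    if not np.any(~obs):
        return counts.copy(), set()
    if obs.sum() < 4:
        raise ValueError("smoothing-spline imputation needs >= 4 observed seasons")

    first, last = seasons[obs][0], seasons[obs][-1]
    missing = np.where(~obs)[0]
    interior = missing[(seasons[missing] > first) & (seasons[missing] < last)]
    edge = set(missing) - set(interior)
    if edge and on_edge_gap == "raise":
        bad = ", ".join(str(int(seasons[i])) for i in sorted(edge))
        raise ValueError(f"extrapolation refused for seasons outside observed span: {bad}")

    filled = counts.copy()
    if interior.size:
        lam = None if lambda_rule == "gcv" else float(lambda_rule)
        spline = fit_smoothing_spline(seasons[obs], counts[obs], lam=lam)
        filled[interior] = np.maximum(spline(seasons[interior]), 0.0)
    return filled, {int(seasons[i]) for i in interior}


def aggregate_partitions(
    series: ColonySeries, lambda_rule: str | float = "gcv"
) -> ColonySeries:
    """Collapse a partitioned colony to totals, imputing interior gaps.

    For each season the total is the sum over partitions, using
    :func:`interpolate_partition` output where a partition count is missing
    mid-series.  Seasons flagged ``interpolated`` when any partition value was
    imputed; seasons where imputation was refused (gap at a partition's edge)
    are left missing.
    """
    if not series.partitions:
        raise ValueError(f"{series.colony_id}: no partitions to aggregate")

    filled_parts, imputed_any = {}, np.zeros(series.seasons.shape, dtype=bool)
    for label, vals in series.partitions.items():
        filled, imputed = interpolate_partition(
            series.seasons, vals, lambda_rule=lambda_rule, on_edge_gap="skip"
        )
        filled_parts[label] = filled
        imputed_any |= np.isin(series.seasons, sorted(imputed))

    stacked = np.vstack(list(filled_parts.values()))
    totals = np.where(np.isnan(stacked).any(axis=0), np.nan, stacked.sum(axis=0))
    flags = imputed_any & ~np.isnan(totals)
    return ColonySeries(
        series.colony_id, series.region, series.seasons, totals,
        interpolated_flags=flags,
    )
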