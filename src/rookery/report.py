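"""Summary tables and regional share arithmetic.

Reproduces the headline census summary: per-colony mean counts, the s
amplitude index, survey totals and contiguity, plus regional totals —
grand total of mean counts, the southern metapopulation's share, the largest
colony's share of the southern sum, and latest-count/mean ratios.

Rounding follows census-report convention: shares to the nearest whole
percent, ratios to one decimal place.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diagnostics import s_index
from .series import ColonySeries


def _longest_run(seasons: np.ndarray) -> int:
    if seasons.size == 0:
        return 0
    best = run = 1
    for d in np.diff(seasons):
        run = run + 1 if d == 1 else 1
        best = max(best, run)
    return int(best)


def summary_table(
    colonies: Iterable[ColonySeries], latest_season: int | None = None
) -> pd.DataFrame:
    """One row per colony: mean count, s, N surveys, longest contiguous run.

    ``latest_count`` is the count at ``latest_season`` when given (NaN if the
    colony was not surveyed then), otherwise the most recent observed count.
    Means include interpolated-total seasons; s needs >= 2 positive counts
    and is NaN otherwise.
    """
    rows = []
    for col in colonies:
        seas, cnt = col.observed()
        if seas.size == 0:
            raise ValueError(f"{col.colony_id}: no observed seasons")
        if latest_season is None:
            latest = cnt[-1]
        else:
            hit = np.where(seas == latest_season)[0]
            latest = cnt[hit[0]] if hit.size else np.nan
        try:
            s = s_index(col)
        except ValueError:
            s = np.nan
        rows.append({
            "colony": col.colony_id,
            "region": col.region,
            "mean_count": float(cnt.mean()),
            "s": s,
            "n_surveys": int(seas.size),
            "n_contiguous": _longest_run(seas),
            "latest_count": latest,
        })
    return pd.DataFrame(rows)


def regional_totals(
    rows: pd.DataFrame,
    southern_ids: Sequence[str],
    largest_id: str,
    ratio_ids: Sequence[str] | None = None,
) -> dict:
    """Regional share arithmetic from a summary table.

    Accepts :func:`summary_table` output or any DataFrame with ``colony`` and
    ``mean_count`` columns (``latest_count`` — or ``count_2012`` — needed for
    the ratio report).

    Returns grand total of mean counts, the southern colonies' share of it
    (percent, nearest integer), ``largest_id``'s share of the southern sum
    likewise, and for ``ratio_ids`` the ratio of their combined latest count
    to their combined mean (1 dp) plus per-colony ratios.
    """
    df = rows.set_index("colony")
    missing = set(southern_ids) - set(df.index)
    if missing:
        raise ValueError(f"unknown southern colonies: {sorted(missing)}")
    latest_col = "latest_count" if "latest_count" in df else "count_2012"

    total = float(df["mean_count"].sum())
    southern = float(df.loc[list(southern_ids), "mean_count"].sum())
    largest = float(df.loc[largest_id, "mean_count"])
    out = {
        "grand_total": total,
        "southern_total": southern,
        "southern_share_pct": int(round(100.0 * southern / total)),
        "largest_share_of_southern_pct": int(round(100.0 * largest / southern)),
    }
    if ratio_ids is not None:
        if latest_col not in df:
            raise ValueError("latest counts required for the ratio report")
        sub = df.loc[list(ratio_ids)]
        if sub[latest_col].isna().any():
            bad = sub.index[sub[latest_col].isna()].tolist()
            raise ValueError(f"latest count missing for {bad}")
        out["latest_to_mean_ratio"] = round(
            float(sub[latest_col].sum() / sub["mean_count"].sum()), 1
        )
        out["per_colony_ratios"] = {
            c: round(float(r[latest_col] / r["mean_count"]), 1)
            for c, r in sub.iterrows()
        }
    return out
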