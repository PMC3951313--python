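"""Core container for a single colony's census time series.

A colony census is an annual count of occupied nesting territories
(breeding pairs), labelled by the calendar year containing the ~1 December
survey date (so the 2001/02 austral season is season 2001).  Some colonies
are counted as the sum of named partitions (sub-colonies); some seasons are
missing entirely; some partition counts are missing within an otherwise
surveyed season.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("southern", "victoria_land")


@dataclass
class ColonySeries:
    """One colony's census series on a common season axis.

    Parameters
    ----------
    colony_id
        Short label, e.g. ``"Cape Bird"``.
    region
        ``"southern"`` (Ross/Beaufort island metapopulation) or
        ``"victoria_land"``.
    seasons
        Strictly increasing census years.  Seasons never surveyed need not
        appear at all; seasons surveyed but with a missing count appear with
        a NaN count.
    counts
        Colony totals aligned with ``seasons``; NaN marks a missing total.
    partitions
        Optional mapping of partition label to per-season counts (NaN where
        that partition was not counted), each aligned with ``seasons``.
    interpolated_flags
        Per-season marker: True when the total includes at least one
        spline-imputed partition value.
    """

    colony_id: str
    region: str
    seasons: np.ndarray
    counts: np.ndarray
    partitions: dict[str, np.ndarray] | None = None
    interpolated_flags: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seasons = np.asarray(self.seasons, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.seasons.ndim != 1 or self.counts.shape != self.seasons.shape:
            raise ValueError("seasons and counts must be 1-D and aligned")
        if self.seasons.size and np.any(np.diff(self.seasons) <= 0):
            raise ValueError(f"{self.colony_id}: seasons must be strictly increasing")
        obs = ~np.isnan(self.counts)
        if np.any(self.counts[obs] < 0) or np.any(~np.isfinite(self.counts[obs])):
            raise ValueError(f"{self.colony_id}: counts must be finite and >= 0")
        if self.partitions is not None:
            self.partitions = {
                k: np.asarray(v, dtype=float) for k, v in self.partitions.items()
            }
            for k, v in self.partitions.items():
                if v.shape != self.seasons.shape:
                    raise ValueError(f"{self.colony_id}: partition {k!r} misaligned")
        if self.interpolated_flags is None:
            self.interpolated_flags = np.zeros(self.seasons.shape, dtype=bool)
        else:
            self.interpolated_flags = np.asarray(self.interpolated_flags, dtype=bool)

    # -- convenience views -------------------------------------------------

    @property
    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.counts)

    @property
    def n_surveys(self) -> int:
        return int(self.observed_mask.sum())

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(seasons, counts) restricted to seasons with a total."""
        m = self.observed_mask
        return self.seasons[m], self.counts[m]

    def longest_contiguous_run(self, positive: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Longest run of consecutive annual surveys (seasons, counts).

        With ``positive=True`` a zero count breaks the run, since log-scale
        diagnostics need strictly positive counts.
        """
        seas, cnt = self.observed()
        if positive:
            keep = cnt > 0
            seas, cnt = seas[keep], cnt[keep]
        if seas.size == 0:
            return seas, cnt
        # split wherever the season step exceeds one year
        breaks = np.where(np.diff(seas) != 1)[0] + 1
        best = max(np.split(np.arange(seas.size), breaks), key=len)
        return seas[best], cnt[best]

    def subset(self, season_lo: int, season_hi: int) -> "ColonySeries":
        m = (self.seasons >= season_lo) & (self.seasons <= season_hi)
        return ColonySeries(
            self.colony_id,
            self.region,
            self.seasons[m],
            self.counts[m],
            partitions=None if self.partitions is None
            else {k: v[m] for k, v in self.partitions.items()},
            interpolated_flags=self.interpolated_flags[m],
        )
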