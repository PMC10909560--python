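"""Area x indicator x time percentage panels.

The observed data of the multi-trajectory model is a three-way array of
percentage indicators: ``values[i, k, t]`` is indicator ``k`` for area ``i``
at time point ``t``, on the 0-100 scale.  A boolean ``mask`` of the same
shape records which cells were actually observed; census releases do not
provide every indicator at every time point (four of the six migration
indicators are unavailable at the first census here), and a zero denominator
also yields an unobserved cell.  Unobserved cells carry NaN and contribute
nothing to any likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical names of the six migration indicators, in model order:
#: shares of residents who moved in from within the country / from abroad,
#: age-band shares of in-movers, and tenure shares of in-moving households.
INDICATORS: tuple[str, ...] = (
    "internal_inmovers_pct",
    "international_inmovers_pct",
    "inmovers_18_24_pct",
    "inmovers_65plus_pct",
    "inmover_owner_pct",
    "inmover_social_pct",
)

LONG_COLUMNS = ["area_id", "year", "indicator", "value", "missing_flag"]


@dataclass
class IndicatorPanel:
    """Percentage indicators for N areas, K indicators, T time points.

    Parameters
    ----------
    values:
        Float array of shape ``(N, K, T)``; NaN where unobserved.
    mask:
        Boolean array of shape ``(N, K, T)``; True where observed.
    area_ids:
        Length-N array of area identifiers.
    years:
        Length-T array of calendar years; trajectories are fitted on the
        coded times ``0 .. T-1`` (equally spaced decadal censuses).
    indicators:
        Length-K tuple of indicator names.
    """

    values: np.ndarray
    mask: np.ndarray
    area_ids: np.ndarray
    years: np.ndarray
    indicators: tuple[str, ...] = INDICATORS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.area_ids = np.asarray(self.area_ids)
        self.years = np.asarray(self.years)
        self.indicators = tuple(self.indicators)
        n, k, t = self.values.shape
        if self.mask.shape != (n, k, t):
            raise ValueError("mask shape does not match values")
        if len(self.area_ids) != n:
            raise ValueError("area_ids length does not match values")
        if len(self.years) != t:
            raise ValueError("years length does not match values")
        if len(self.indicators) != k:
            raise ValueError("indicator names do not match values")
        if len(np.unique(self.area_ids)) != n:
            raise ValueError("duplicate area_ids")
        obs = self.values[self.mask]
        if obs.size and (not np.isfinite(obs).all() or obs.min() < 0 or obs.max() > 100):
            raise ValueError("observed values must be finite percentages in [0, 100]")
        # unobserved cells are NaN by construction
        self.values = np.where(self.mask, self.values, np.nan)

    # -- shape helpers -----------------------------------------------------

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    @property
    def n_obs(self) -> int:
        """Number of observed (non-missing) cells."""
        return int(self.mask.sum())

    @property
    def times(self) -> np.ndarray:
        """Coded time axis 0 .. T-1 used by the polynomial trajectories."""
        return np.arange(self.n_timepoints, dtype=float)

    # -- long-format interchange ------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: area_id, year, indicator, value, missing_flag."""
        n, k, t = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.area_ids, self.indicators, self.years],
            names=["area_id", "indicator", "year"],
        )
        df = pd.DataFrame(
            {
                "value": self.values.ravel(),
                "missing_flag": (~self.mask).ravel().astype(int),
            },
            index=idx,
        ).reset_index()
        df.loc[df["missing_flag"] == 1, "value"] = np.nan
        return df[LONG_COLUMNS]

    @classmethod
    def from_long(cls, df: pd.DataFrame, indicators: tuple[str, ...] | None = None) -> "IndicatorPanel":
        """Build a panel from the long-format interchange frame."""
        missing_cols = set(LONG_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValueError(f"long panel missing columns: {sorted(missing_cols)}")
        if indicators is None:
            seen = list(dict.fromkeys(df["indicator"]))
            indicators = tuple(i for i in INDICATORS if i in seen) or tuple(seen)
        area_ids = np.array(sorted(df["area_id"].unique()))
        years = np.array(sorted(df["year"].unique()))
        shape = (len(area_ids), len(indicators), len(years))
        values = np.full(shape, np.nan)
        mask = np.zeros(shape, dtype=bool)
        a_pos = {a: i for i, a in enumerate(area_ids)}
        k_pos = {k: i for i, k in enumerate(indicators)}
        t_pos = {y: i for i, y in enumerate(years)}
        if df.duplicated(["area_id", "year", "indicator"]).any():
            raise ValueError("duplicate (area_id, year, indicator) rows")
        for row in df.itertuples(index=False):
            i, k, t = a_pos[row.area_id], k_pos[row.indicator], t_pos[row.year]
            if not row.missing_flag:
                values[i, k, t] = row.value
                mask[i, k, t] = True
        return cls(values, mask, area_ids, years, indicators)

    def subset_areas(self, index: np.ndarray) -> "IndicatorPanel":
        return IndicatorPanel(
            self.values[index], self.mask[index], self.area_ids[index], self.years, self.indicators
        )
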