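"""Build the six migration indicators from census-style count tables.

A count table holds, per (area, year): usual residents, internal and
international in-movers, in-movers aged 18-24 and 65+, and in-moving
households (total / owner-occupying / in social housing).  From these the
six percentage indicators are formed:

1. internal in-movers as % of usual residents
2. international in-movers as % of usual residents
3. in-movers aged 18-24 as % of all in-movers (internal + international)
4. in-movers aged 65+ as % of all in-movers
5. owner-occupying in-moving households as % of in-moving households
6. social-housing in-moving households as % of in-moving households

A zero denominator or an absent count yields a missing indicator cell, not
a zero: an unobserved share and a share of zero mean different things to
the likelihood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import INDICATORS, IndicatorPanel

COUNT_COLUMNS = [
    "usual_residents",
    "internal_inmovers",
    "international_inmovers",
    "inmovers_18_24",
    "inmovers_65plus",
    "inmover_households_total",
    "inmover_households_owner",
    "inmover_households_social",
]

#: Count columns scaled by the optional per-(area, year) adjustment factor
#: for missing/incomplete origin addresses.  International in-mover counts
#: are left unadjusted, as are the denominators based on usual residents.
ADJUSTABLE_COLUMNS = [
    "internal_inmovers",
    "inmovers_18_24",
    "inmovers_65plus",
    "inmover_households_total",
    "inmover_households_owner",
    "inmover_households_social",
]


def share_pct(numerator, denominator):
    """Percentage share ``100 * numerator / denominator``; NaN when empty.

    Accepts scalars or arrays of nonnegative counts.  A zero denominator
    gives a missing share (NaN) rather than zero or an error.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if (num < 0).any() or (den < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, 100.0 * num / den, np.nan)
    if np.isscalar(numerator) and np.isscalar(denominator):
        return float(out)
    return out


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Check a wide count table: keys, nonnegativity, component consistency."""
    required = {"area_id", "year"}
    if not required.issubset(df.columns):
        raise ValueError("count table requires area_id and year columns")
    if df.duplicated(["area_id", "year"]).any():
        dup = df.loc[df.duplicated(["area_id", "year"]), ["area_id", "year"]]
        raise ValueError(f"duplicate (area_id, year) keys: {dup.head(5).to_dict('records')}")
    present = [c for c in COUNT_COLUMNS if c in df.columns]
    for c in present:
        vals = df[c].dropna()
        if (vals < 0).any():
            raise ValueError(f"negative counts in column {c}")

    def _leq(small: str, big_value: pd.Series, label: str) -> None:
        if small not in df.columns:
            return
        both = df[small].notna() & big_value.notna()
        if (df.loc[both, small] > big_value[both] + 1e-9).any():
            raise ValueError(f"component count exceeds its total: {label}")

    if {"internal_inmovers", "international_inmovers"}.issubset(df.columns):
        total_inmovers = df["internal_inmovers"] + df["international_inmovers"]
        _leq("inmovers_18_24", total_inmovers, "inmovers_18_24 > in-movers")
        _leq("inmovers_65plus", total_inmovers, "inmovers_65plus > in-movers")
    if "inmover_households_total" in df.columns:
        _leq("inmover_households_owner", df["inmover_households_total"], "owner households > households")
        _leq("inmover_households_social", df["inmover_households_total"], "social households > households")
    return df


def build_panel(counts: pd.DataFrame, adjustment: pd.Series | None = None) -> IndicatorPanel:
    """Compute the six-indicator panel from a wide (area, year) count table.

    ``adjustment`` optionally pre-scales the origin-address-adjustable counts
    per (area, year) row (aligned on the table's row order or on a
    ``(area_id, year)`` MultiIndex); the default is no adjustment.  Count
    columns absent from the input — e.g. age and tenure at the first census —
    become missing indicator cells for the corresponding years.
    """
    df = validate_counts(counts.copy())
    if adjustment is not None:
        adj = np.asarray(
            adjustment.reindex(pd.MultiIndex.from_frame(df[["area_id", "year"]])).to_numpy()
            if isinstance(adjustment.index, pd.MultiIndex)
            else adjustment,
            dtype=float,
        )
        if len(adj) != len(df):
            raise ValueError("adjustment must align with the count rows")
        for c in ADJUSTABLE_COLUMNS:
            if c in df.columns:
                df[c] = df[c] * adj

    area_ids = np.array(sorted(df["area_id"].unique()))
    years = np.array(sorted(df["year"].unique()))
    n, t = len(area_ids), len(years)
    grid = pd.DataFrame(
        {"area_id": np.repeat(area_ids, t), "year": np.tile(years, n)}
    ).merge(df, on=["area_id", "year"], how="left")

    def col(name: str) -> np.ndarray:
        if name in grid.columns:
            return grid[name].to_numpy(dtype=float)
        return np.full(len(grid), np.nan)

    residents = col("usual_residents")
    internal = col("internal_inmovers")
    international = col("international_inmovers")
    inmovers = internal + international
    households = col("inmover_households_total")

    def safe_share(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(np.nan_to_num(den) > 0, 100.0 * num / den, np.nan)

    cols = [
        safe_share(internal, residents),
        safe_share(international, residents),
        safe_share(col("inmovers_18_24"), inmovers),
        safe_share(col("inmovers_65plus"), inmovers),
        safe_share(col("inmover_households_owner"), households),
        safe_share(col("inmover_households_social"), households),
    ]
    flat = np.stack(cols, axis=1)  # (N*T, 6)
    values = flat.reshape(n, t, 6).transpose(0, 2, 1)  # (N, K, T)
    mask = np.isfinite(values)
    return IndicatorPanel(values=values, mask=mask, area_ids=area_ids, years=years, indicators=INDICATORS)
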