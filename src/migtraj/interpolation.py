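"""Areal-weighting conversion of counts between boundary systems.

Census geographies change between censuses; counts published on one set of
area boundaries must be moved onto another before a longitudinal model can
be fitted.  The standard technique is areal weighting: each source area's
count is split across overlapping target areas in proportion to supplied
overlap weights.  When a lookup provides no proportions for a source, its
count is divided equally among its targets.  Counts are converted before
any ratio indicator is computed — interpolating ratios directly would not
conserve mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WEIGHT_SUM_TOL = 1e-9


class UnmappedSourceError(KeyError):
    """Raised when source areas have no rows in the lookup table."""

    def __init__(self, missing: list):
        self.missing = list(missing)
        super().__init__(f"sources absent from lookup: {self.missing[:20]}")


@dataclass
class AreaLookup:
    """Source-to-target correspondence rows ``(source_id, target_id[, weight])``.

    Each source must either carry weights on all of its rows (summing to one)
    or on none of them (equal split applies).  Mixing the two regimes within
    one source is rejected.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        required = {"source_id", "target_id"}
        if not required.issubset(df.columns):
            raise ValueError("lookup requires source_id and target_id columns")
        if "weight" not in df.columns:
            df["weight"] = np.nan
        if df.duplicated(["source_id", "target_id"]).any():
            raise ValueError("duplicate (source_id, target_id) pairs in lookup")
        has_w = df["weight"].notna()
        w = df.loc[has_w, "weight"]
        if ((w < 0) | (w > 1)).any():
            raise ValueError("weights must lie in [0, 1]")
        per_source = df.groupby("source_id")["weight"]
        frac = per_source.apply(lambda s: s.notna().mean())
        mixed = frac[(frac > 0) & (frac < 1)]
        if len(mixed):
            raise ValueError(f"sources mix weighted and weight-free rows: {list(mixed.index)[:10]}")
        sums = df.loc[has_w].groupby("source_id")["weight"].sum()
        bad = sums[(sums - 1.0).abs() > WEIGHT_SUM_TOL]
        if len(bad):
            raise ValueError(f"per-source weights must sum to 1: {dict(bad.head(10))}")
        self.table = df[["source_id", "target_id", "weight"]].reset_index(drop=True)

    @property
    def sources(self) -> np.ndarray:
        return self.table["source_id"].unique()

    def effective_weights(self) -> pd.DataFrame:
        """Rows with the weight actually applied (equal split where absent)."""
        df = self.table.copy()
        n_targets = df.groupby("source_id")["target_id"].transform("count")
        df["weight"] = df["weight"].fillna(1.0 / n_targets)
        return df

    @classmethod
    def from_csv(cls, path) -> "AreaLookup":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def convert_counts(values: pd.DataFrame, lookup: AreaLookup) -> pd.DataFrame:
    """Convert count columns from source areas onto target areas.

    ``values`` is indexed by source id (or carries a ``source_id``/``area_id``
    column); every numeric column is transferred as
    ``target = sum_source weight * source``.  Fractional results are kept —
    downstream percentage indicators are scale-free.
    """
    df = values.copy()
    if "source_id" in df.columns:
        df = df.set_index("source_id")
    elif "area_id" in df.columns:
        df = df.set_index("area_id")
    missing = [s for s in df.index if s not in set(lookup.table["source_id"])]
    if missing:
        raise UnmappedSourceError(missing)
    eff = lookup.effective_weights()
    eff = eff[eff["source_id"].isin(df.index)]
    joined = eff.merge(df, left_on="source_id", right_index=True, how="left")
    num_cols = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    for c in num_cols:
        joined[c] = joined[c] * joined["weight"]
    out = joined.groupby("target_id")[num_cols].sum()
    out.index.name = "target_id"
    return out


def validate_conversion(
    candidate: pd.DataFrame, reference: pd.DataFrame, tolerance: float
) -> pd.DataFrame:
    """Per-area relative discrepancy report between two target-level tables.

    A manually built conversion is accepted only if it reproduces a trusted
    conversion closely on shared data; this flags every area whose worst
    per-column relative discrepancy exceeds ``tolerance``.  The returned
    frame has columns ``rel_discrepancy`` and ``flagged`` and carries a
    ``summary`` attribute with total and flagged area counts.
    """
    if set(candidate.index) != set(reference.index):
        raise ValueError("candidate and reference must cover the same target areas")
    ref = reference.loc[candidate.index]
    cols = [c for c in candidate.columns if c in ref.columns]
    if not cols:
        raise ValueError("no shared columns to compare")
    cand_v = candidate[cols].to_numpy(dtype=float)
    ref_v = ref[cols].to_numpy(dtype=float)
    denom = np.maximum(np.abs(ref_v), 1e-12)
    rel = np.abs(cand_v - ref_v) / denom
    rel[(cand_v == ref_v)] = 0.0
    worst = rel.max(axis=1)
    report = pd.DataFrame(
        {"rel_discrepancy": worst, "flagged": worst > tolerance}, index=candidate.index
    )
    report.attrs["summary"] = {
        "n_areas": int(len(report)),
        "n_flagged": int(report["flagged"].sum()),
        "tolerance": float(tolerance),
    }
    return report
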