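"""Association between two categorical area classifications.

A new classification is validated against existing ones by cross-tabulating
the two labelings over a shared geography, testing independence with a
Pearson chi-square test, and summarising the strength of association with
Cramér's V (``sqrt(chi2 / (n * (min(r, c) - 1)))``, scaled to [0, 1]).
A correspondence report flags label pairs of exceptionally strong or weak
overlap.  When the two classifications live on different boundary systems,
labels are transferred by majority areal weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interpolation import AreaLookup


@dataclass
class AssociationResult:
    """Cross-tab with its chi-square test and Cramér's V."""

    crosstab: pd.DataFrame
    chi2: float
    df: int
    p: float
    cramers_v: float
    n: int


def cross_tabulate(labels_a, labels_b) -> pd.DataFrame:
    """Count table of label pairs; inputs must cover the same areas.

    Accepts aligned arrays, or `pandas` Series indexed by area id (aligned
    on the shared key set; mismatched key sets are rejected).
    """
    if isinstance(labels_a, pd.Series) and isinstance(labels_b, pd.Series):
        if set(labels_a.index) != set(labels_b.index):
            raise ValueError("label tables cover different area sets")
        labels_b = labels_b.reindex(labels_a.index)
        a, b = labels_a.to_numpy(), labels_b.to_numpy()
    else:
        a, b = np.asarray(labels_a), np.asarray(labels_b)
        if len(a) != len(b):
            raise ValueError("labelings differ in length")
    tab = pd.crosstab(pd.Series(a, name="a"), pd.Series(b, name="b"))
    return tab


def chi_square_independence(crosstab: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Empty rows/columns are dropped with a warning before testing; no
    continuity correction is applied.  Returns ``(chi2, df, p)`` with
    ``df = (r - 1)(c - 1)``.
    """
    tab = np.asarray(crosstab, dtype=float)
    keep_r = tab.sum(axis=1) > 0
    keep_c = tab.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("dropping empty rows/columns before chi-square test")
        tab = tab[keep_r][:, keep_c]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping empty margins")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(df), float(p)


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Cramér's V from a chi-square statistic and table dimensions."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if min(r, c) < 2:
        raise ValueError("Cramér's V needs at least two categories per margin")
    v = np.sqrt(chi2 / (n * (min(r, c) - 1)))
    return float(min(1.0, max(0.0, v)))


def associate(labels_a, labels_b) -> AssociationResult:
    """Full association analysis of two labelings: cross-tab, chi-square, V."""
    tab = cross_tabulate(labels_a, labels_b)
    chi2, df, p = chi_square_independence(tab)
    n = int(np.asarray(tab).sum())
    v = cramers_v(chi2, n, tab.shape[0], tab.shape[1])
    return AssociationResult(crosstab=tab, chi2=chi2, df=df, p=p, cramers_v=v, n=n)


def correspondence_report(
    crosstab: pd.DataFrame, strong_threshold: float = 0.5, split_band: float = 0.1
) -> pd.DataFrame:
    """Row-wise overlap shares with strong / split flags (advisory).

    Each row of the cross-tab is normalised to shares; a cell above
    ``strong_threshold`` is a strong overlap, and a row whose shares all lie
    within ``split_band`` of uniform is flagged as split across columns.
    """
    tab = crosstab.astype(float)
    if tab.size == 0:
        raise ValueError("empty cross-tab")
    totals = tab.sum(axis=1)
    shares = tab.div(totals.replace(0, np.nan), axis=0)
    c = tab.shape[1]
    out = shares.copy()
    out["strong_with"] = [
        "|".join(str(col) for col in shares.columns[(shares.loc[r] > strong_threshold).fillna(False)])
        for r in shares.index
    ]
    out["split"] = ((shares.sub(1.0 / c)).abs().max(axis=1) <= split_band).fillna(False)
    return out


def transfer_labels(labels: pd.Series, lookup: AreaLookup) -> pd.Series:
    """Carry source-area labels onto target areas by majority areal weight.

    Each target takes the label whose source rows contribute the largest
    total weight; ties resolve to the lowest label.  Weight-free sources
    contribute equal splits.
    """
    eff = lookup.effective_weights()
    missing = sorted(set(eff["source_id"]) - set(labels.index))
    if missing:
        raise ValueError(f"labels missing for sources: {missing[:10]}")
    eff = eff.assign(label=eff["source_id"].map(labels))
    weight_by = (
        eff.groupby(["target_id", "label"])["weight"].sum().reset_index()
    )
    weight_by = weight_by.sort_values(["target_id", "weight", "label"], ascending=[True, False, True])
    winners = weight_by.drop_duplicates("target_id", keep="first")
    return winners.set_index("target_id")["label"].sort_index()
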