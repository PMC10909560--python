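"""Classify-analyse profiling of the fitted clusters.

After enumeration, each area is hard-assigned to its modal latent group and
the groups are treated as known classes: per-cluster means of descriptive
attributes, one-way ANOVA of each attribute across clusters, and the
geographic make-up of each cluster (urban share and regional distribution).
Hard assignment ignores membership uncertainty — with the near-1 assignment
probabilities typical of well-separated trajectory groups this matters
little, and a posterior-weighted variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Classification:
    """Hard cluster labels (1..G) per area, with optional posteriors and tags."""

    area_ids: np.ndarray
    labels: np.ndarray
    posteriors: np.ndarray | None = None
    regions: np.ndarray | None = None
    urban: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_ids = np.asarray(self.area_ids)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.area_ids):
            raise ValueError("one label per area required")
        if self.labels.min() < 1:
            raise ValueError("labels are 1-based cluster indices")
        if self.posteriors is not None:
            self.posteriors = np.asarray(self.posteriors, dtype=float)
            if self.posteriors.shape[0] != len(self.area_ids):
                raise ValueError("one posterior row per area required")
            if not np.allclose(self.posteriors.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("posterior rows must sum to 1")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    @classmethod
    def from_model(cls, model, regions=None, urban=None) -> "Classification":
        return cls(
            area_ids=model.area_ids,
            labels=model.labels,
            posteriors=model.posteriors,
            regions=regions,
            urban=urban,
        )


@dataclass
class ClusterProfile:
    """Per-cluster attribute means, shares, and ANOVA results."""

    means: pd.DataFrame  # attributes x clusters
    shares_pct: pd.Series  # % of areas per cluster
    anova: pd.DataFrame  # per attribute: F, df1, df2, p
    geography: pd.DataFrame | None = None


def anova_across_clusters(classification: Classification, values: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA of an attribute across clusters.

    Returns ``(F, (df_between, df_within), p)``.  With zero within-cluster
    variance but unequal means, F is infinite and p is reported at the
    machine floor.  Missing attribute values are dropped.
    """
    labels = classification.labels
    v = np.asarray(values, dtype=float)
    keep = np.isfinite(v)
    v, labels = v[keep], labels[keep]
    groups = [v[labels == j] for j in np.unique(labels)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2 or len(v) < 3:
        raise ValueError("ANOVA needs at least two non-empty clusters and three values")
    n = len(v)
    k = len(groups)
    grand = v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0:
        if msb == 0:
            return 0.0, (df1, df2), 1.0
        return float("inf"), (df1, df2), float(np.finfo(float).tiny)
    f_stat = msb / msw
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), (df1, df2), p


def profile(
    classification: Classification,
    attributes: pd.DataFrame,
    weighted: bool = False,
    anova_alpha: float | None = None,
) -> ClusterProfile:
    """Tabulate per-cluster attribute means, cluster shares, and ANOVA.

    ``attributes`` is indexed by area id (or carries an ``area_id`` column)
    with one numeric column per descriptive attribute; missing values are
    ignored within each cluster.  With ``weighted=True`` means are
    posterior-weighted rather than based on hard assignment.
    """
    attrs = attributes.copy()
    if "area_id" in attrs.columns:
        attrs = attrs.set_index("area_id")
    attrs = attrs.reindex(classification.area_ids)
    clusters = np.arange(1, classification.n_clusters + 1)
    n = len(classification.area_ids)

    means = {}
    for j in clusters:
        if weighted:
            if classification.posteriors is None:
                raise ValueError("weighted profiling requires posteriors")
            w = classification.posteriors[:, j - 1]
            col = {}
            for c in attrs.columns:
                v = attrs[c].to_numpy(dtype=float)
                ok = np.isfinite(v)
                col[c] = float((w[ok] * v[ok]).sum() / w[ok].sum()) if w[ok].sum() > 0 else np.nan
            means[j] = col
        else:
            members = classification.labels == j
            means[j] = attrs.loc[members].mean(numeric_only=True).to_dict()
    means_df = pd.DataFrame(means)
    means_df.columns.name = "cluster"

    counts = pd.Series(
        {j: int((classification.labels == j).sum()) for j in clusters}, name="n_areas"
    )
    shares = 100.0 * counts / n
    shares.name = "share_pct"

    rows = {}
    for c in attrs.columns:
        try:
            f_stat, (df1, df2), p = anova_across_clusters(classification, attrs[c].to_numpy(dtype=float))
        except ValueError:
            f_stat, df1, df2, p = np.nan, np.nan, np.nan, np.nan
        row = {"F": f_stat, "df_between": df1, "df_within": df2, "p": p}
        if anova_alpha is not None:
            row["significant"] = p < anova_alpha if np.isfinite(p) else np.nan
        rows[c] = row
    anova_df = pd.DataFrame(rows).T

    geo = None
    if classification.regions is not None or classification.urban is not None:
        geo = geography_summary(classification)
    return ClusterProfile(means=means_df, shares_pct=shares, anova=anova_df, geography=geo)


def geography_summary(
    classification: Classification, allowed_regions=None
) -> pd.DataFrame:
    """Urban share and regional distribution per cluster (rows sum to 100).

    ``allowed_regions``, when given, is the set of legal region tags;
    unrecognised tags are rejected with the offending values listed.
    """
    if classification.regions is None:
        raise ValueError("classification carries no region tags")
    regions = np.asarray(classification.regions)
    if allowed_regions is not None:
        unknown = sorted(set(regions) - set(allowed_regions))
        if unknown:
            raise ValueError(f"unknown region tags: {unknown}")
    clusters = np.arange(1, classification.n_clusters + 1)
    region_names = sorted(set(regions))
    rows = {}
    for j in clusters:
        members = classification.labels == j
        total = members.sum()
        row = {}
        if classification.urban is not None:
            urb = np.asarray(classification.urban, dtype=bool)
            row["pct_urban"] = 100.0 * urb[members].mean() if total else np.nan
        for r in region_names:
            row[f"pct_in_{r}"] = (
                100.0 * ((regions == r) & members).sum() / total if total else np.nan
            )
        rows[j] = row
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out
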