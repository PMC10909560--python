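"""CSV/JSON codecs for panels, lookups, labels and fitted models.

All tabular artifacts are plain UTF-8 CSV with a header row and '.' decimal
separator.  The panel dialect is long format — one row per (area, year,
indicator) cell with a ``missing_flag`` column — so that the availability
pattern survives a round trip.  Fitted models serialise to a JSON document
holding parameters and fit metadata; posteriors and labels live in separate
CSVs keyed by area id.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .gbmt import FittedModel
from .interpolation import AreaLookup
from .panel import LONG_COLUMNS, IndicatorPanel


def write_panel(panel: IndicatorPanel, path) -> None:
    panel.to_long().to_csv(path, index=False)


def read_panel(path) -> IndicatorPanel:
    df = pd.read_csv(path, float_precision="round_trip")
    missing_cols = set(LONG_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    observed = df["missing_flag"] == 0
    bad = observed & (~df["value"].between(0, 100) | df["value"].isna())
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"{path}: observed values outside [0, 100] at lines {lines}")
    return IndicatorPanel.from_long(df)


def read_lookup(path) -> AreaLookup:
    return AreaLookup.from_csv(path)


def write_lookup(lookup: AreaLookup, path) -> None:
    lookup.to_csv(path)


def write_labels(area_ids, labels, path) -> None:
    pd.DataFrame({"area_id": np.asarray(area_ids), "label": np.asarray(labels)}).to_csv(
        path, index=False
    )


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path)
    if not {"area_id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: label table requires area_id and label columns")
    if df["area_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate area ids")
    return df.set_index("area_id")["label"]


def write_posteriors(model: FittedModel, path) -> None:
    cols = {f"p_group{j + 1}": model.posteriors[:, j] for j in range(model.n_groups)}
    pd.DataFrame({"area_id": model.area_ids, "label": model.labels, **cols}).to_csv(
        path, index=False
    )


def write_model_json(model: FittedModel, path, extra: dict | None = None) -> None:
    doc = model.to_dict()
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def read_model_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
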