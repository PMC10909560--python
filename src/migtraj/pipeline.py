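"""End-to-end pipeline: counts -> indicators -> enumeration -> classification.

Binds the stages into the full analysis: optional boundary conversion of
raw counts, indicator construction, class enumeration over a range of group
counts, polynomial-order adjustment of the chosen model, classify-analyse
profiling, and optional comparison with an external classification.  Every
artifact directory carries a run log with the seed and a hash of the
configuration, so identical configurations give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import indicators as ind
from . import io as mio
from .comparison import associate
from .gbmt import ModelSpec
from .interpolation import convert_counts
from .profiling import Classification, profile
from .selection import adjust_polynomial_orders, diagnose, enumerate_models

logger = logging.getLogger("migtraj")


@dataclass
class PipelineConfig:
    """Paths and parameters driving :func:`run_pipeline`."""

    output_dir: str
    panel_path: str | None = None
    counts_path: str | None = None
    lookup_path: str | None = None
    compare_labels_path: str | None = None
    attributes_path: str | None = None
    g_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    orders: int = 3
    variance_mode: str = "shared"
    tol: float = 1e-8
    max_iter: int = 500
    n_starts: int = 3
    seed: int = 0
    adjust_alpha: float | None = 0.05
    select_g: int | None = None  # None: pick best bic_obs

    def __post_init__(self) -> None:
        if self.panel_path is None and self.counts_path is None:
            raise ValueError("config needs panel_path or counts_path")
        self.g_range = tuple(int(g) for g in self.g_range)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def digest(self) -> str:
        # hash the analytic configuration; where artifacts land is excluded
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured pipeline; returns the artifact bundle.

    Writes, under ``output_dir``: the built panel, the enumeration table,
    the selected (and order-adjusted) model JSON, labels and posteriors,
    the cluster profile, any comparison result, and ``run_log.json`` with
    seed and config hash.  Stage failures raise with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_digest": config.digest(), "seed": config.seed}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # -- inputs ----------------------------------------------------------
    if config.panel_path is not None:
        panel = stage("read_panel", lambda: mio.read_panel(config.panel_path))
    else:
        def _build():
            counts = pd.read_csv(config.counts_path)
            if config.lookup_path is not None:
                lookup = mio.read_lookup(config.lookup_path)
                converted = []
                for year, grp in counts.groupby("year"):
                    conv = convert_counts(grp.drop(columns=["year"]), lookup)
                    conv = conv.reset_index().rename(columns={"target_id": "area_id"})
                    conv["year"] = year
                    converted.append(conv)
                counts = pd.concat(converted, ignore_index=True)
            return ind.build_panel(counts)

        panel = stage("build_indicators", _build)
    mio.write_panel(panel, out / "panel.csv")
    bundle["panel"] = panel

    # -- enumeration -----------------------------------------------------
    template = ModelSpec(
        n_groups=1,
        orders=config.orders,
        variance_mode=config.variance_mode,
        tol=config.tol,
        max_iter=config.max_iter,
        n_starts=config.n_starts,
        seed=config.seed,
    )
    table = stage("enumerate", lambda: enumerate_models(panel, config.g_range, template))
    table.to_frame().to_csv(out / "enumeration.csv", index=False)
    bundle["enumeration"] = table

    g_star = config.select_g if config.select_g is not None else table.best_by("bic_obs")
    model = table.models[g_star]
    if config.adjust_alpha is not None:
        model = stage(
            "adjust_orders",
            lambda: adjust_polynomial_orders(panel, model, config.adjust_alpha, template),
        )
    bundle["model"] = model
    bundle["selected_G"] = g_star
    mio.write_model_json(
        model,
        out / "model.json",
        extra={"seed": config.seed, "config_digest": config.digest(), "selected_G": g_star},
    )
    mio.write_posteriors(model, out / "posteriors.csv")
    mio.write_labels(model.area_ids, model.labels, out / "labels.csv")
    diag = diagnose(model)
    bundle["diagnostics"] = diag

    # -- profiling -------------------------------------------------------
    classification = Classification.from_model(model)
    bundle["classification"] = classification
    if config.attributes_path is not None:
        attrs = stage("read_attributes", lambda: pd.read_csv(config.attributes_path))
        prof = stage("profile", lambda: profile(classification, attrs))
        prof.means.to_csv(out / "profile_means.csv")
        prof.anova.to_csv(out / "profile_anova.csv")
        bundle["profile"] = prof

    # -- comparison ------------------------------------------------------
    if config.compare_labels_path is not None:
        other = stage("read_compare_labels", lambda: mio.read_labels(config.compare_labels_path))
        ours = pd.Series(model.labels, index=model.area_ids)
        assoc = stage("compare", lambda: associate(ours, other))
        assoc.crosstab.to_csv(out / "comparison_crosstab.csv")
        with open(out / "comparison.json", "w") as fh:
            json.dump(
                {
                    "chi2": assoc.chi2,
                    "df": assoc.df,
                    "p": assoc.p,
                    "cramers_v": assoc.cramers_v,
                    "n": assoc.n,
                },
                fh,
                indent=2,
            )
        bundle["association"] = assoc

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "config_digest": config.digest(),
                "selected_G": g_star,
                "bic_obs": diag.bic_obs,
                "entropy": diag.entropy,
                "n_areas": panel.n_areas,
                "n_obs": panel.n_obs,
            },
            fh,
            indent=2,
        )
    logger.info("pipeline complete: G=%d, bic_obs=%.2f", g_star, diag.bic_obs)
    return bundle
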