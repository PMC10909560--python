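# migtraj

Longitudinal, migration-specific area classification with **group-based
multi-trajectory models** (GBMTM).

Cross-sectional area classifications summarise what places are like at one
moment; they say little about how migration into those places has been
*changing*. `migtraj` classifies small areas (census wards) by the joint
trajectories of six migration indicators across several censuses — the
shares of residents who moved in from within the country and from abroad,
the age profile of in-movers (18–24 and 65+), and the tenure of in-moving
households (owner-occupying and social housing) — so that, say, a
steadily-studentifying ward and a ward with high but declining migration
end up in different classes even when they look identical in one census.

It is a library for quantitative geographers, demographers and
epidemiologists who work with areal census aggregates, plus a thin
`migtraj` command-line wrapper.

## The model

Areas `i = 1..N` belong to one of `G` latent groups with mixing
proportions `π_g`. Conditional on group `g`, each observed indicator value
is independent Gaussian around a polynomial trajectory in coded time
`t = 0..T−1`:

```
y_ikt | group g  ~  Normal( μ_gk(t), σ_k ),      μ_gk(t) = Σ_p β_gkp t^p
```

with one noise scale per indicator (optionally per group and indicator).
Indicator–time cells that a census never published (four of the six
indicators are unavailable at the first time point) are simply absent from
the likelihood. Parameters are estimated by multi-start EM; posterior
memberships `p_ig ∝ π_g · L_ig` give each area a probability of belonging
to each trajectory group, and modal assignment yields the classification.

Model selection over `G` uses the standard trajectory-modelling battery:
BIC (`logL − ½·p·ln n`, under both the observation-count and area-count
conventions) and AIC, normalized entropy, per-group APPA (average
posterior probability of assignment), OCC (odds of correct classification,
`[APPA/(1−APPA)] / [π/(1−π)]`), the assignment/estimate mismatch, and the
smallest-group share. After choosing `G`, non-significant top-order
polynomial terms are backward-eliminated per (group, indicator) using
posterior-weighted Wald tests.

Around the core model the package provides the full pipeline: areal
weighting of counts between boundary systems (with an equal-split fallback
when no proportions exist), construction of the six indicators from raw
count tables, classify-analyse cluster profiling with one-way ANOVA, and
comparison against external classifications via chi-square tests and
Cramér's V. A seeded synthetic-data generator produces panels with known
latent structure so every stage is testable without any census download.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
import migtraj as m

sim = m.generate_panel(m.three_group_spec(n_areas=1000, seed=42))
model = m.fit(sim.panel, m.ModelSpec(n_groups=3, orders=3, seed=0, n_starts=2))
print(np.round(model.pi, 3))
print(adjusted_rand_score(sim.true_labels, model.labels))
```

Running `python examples/simulate_and_fit.py` prints:

```
log likelihood: -43192.7  (converged in 3 EM iterations)
mixing proportions: [0.497 0.285 0.218]  (truth ~ 0.5/0.3/0.2 descending)
adjusted Rand vs true labels: 1.000
noise SDs per indicator: [2.   2.01 1.97 1.98 2.   1.98]  (truth: 2.0 pp)

fitted mean trajectory, group 1, internal in-mover share:
  [59.97 57.94 56.06 54.05] (percent, per census)
```

The mixing proportions match the generating shares to within sampling
error, the adjusted Rand index of 1.0 means every area was returned to its
true group, and the recovered noise scale equals the 2 percentage points
the generator used. The other scripts in `examples/` walk through
enumeration over `G` (`enumerate_groups.py`), building indicators from
count tables (`build_indicators.py`), boundary conversion
(`areal_interpolation.py`), and profiling/comparison
(`profile_and_compare.py`).

A full pipeline — counts → indicators → enumeration → order adjustment →
classification → profiling → comparison — runs from a YAML config via
`migtraj run --config config.yaml`, or from Python with
`migtraj.run_pipeline(PipelineConfig(...))`.

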