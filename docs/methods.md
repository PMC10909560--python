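# Methods

## Model

The classification rests on a finite mixture of multivariate longitudinal
Gaussians. Each area `i` carries observations `y_ikt` for indicator
`k = 1..K` (K = 6 migration percentages) at time points `t = 0..T−1`
(T = 4 decadal censuses, coded with equal spacing — the simplest
identifiable coding for equally spaced waves). Latent group membership
`z_i ∈ {1..G}` has prior `π` on the simplex; conditional on `z_i = g`,

    y_ikt ~ Normal( μ_gk(t), σ_k ),   μ_gk(t) = Σ_{p=0}^{q_gk} β_gkp t^p,

independently across indicators and times. Conditional independence given
group is the standard multi-trajectory assumption: the groups themselves
carry all cross-indicator and cross-time structure.

**Missing data.** Cells are skipped in the likelihood when unobserved
(missing at random). This handles both structural gaps — the four
age/tenure indicators do not exist at the first census — and sporadic gaps
from zero denominators. An unobserved share and a zero share are kept
distinct throughout: a denominator of zero yields a missing cell, never 0.

**Outcome family.** Plain Gaussian on the percentage scale, unstandardized
(trajectories are read in raw percentage points). A censored-normal
variant with bounds at 0/100 was considered and not implemented: a
Tobit-type M-step loses the closed-form updates and the per-iteration
monotonicity guarantee asserted by the test suite, and under the simulated
study conditions the group means sit well inside [0, 100] so clipping is
inactive (the generator counts and reports any clipped draws). This is a
known limitation for real panels with indicators near the boundaries.

**Variance structure.** Default is one `σ_k` per indicator shared across
groups (the convention of the established trajectory-modelling software);
`variance_mode="by_group"` estimates `σ_gk`. Scales are floored at 1e-6 pp
so degenerate zero-noise fits remain finite.

## Estimation

EM with exact steps:

* E-step: posteriors `p_ig ∝ π_g · exp(Σ_observed log φ(y; μ_gk(t), σ))`,
  computed in log space with log-sum-exp so far-outlying areas underflow
  gracefully.
* M-step: `π = mean_i p_ig`; each `β_gk` from posterior-weighted least
  squares of the observed values on the time polynomial (the normal
  equations collapse over areas because the design depends only on `t`);
  `σ` from posterior-weighted residual sums of squares.

Convergence when the log-likelihood improves by less than `tol`
(default 1e-8, relative) or after `max_iter` (default 500) iterations.
The log-likelihood path is stored and checked non-decreasing on every fit.

**Initialisation.** k-means on per-area vectors of time-averaged
indicators (missing-aware; fully-missing features imputed at the column
mean), responsibilities softened to 0.95/0.05. Subsequent starts jitter
the features with half-SD Gaussian noise before clustering. The best
non-degenerate start by log-likelihood is kept; a run is degenerate when a
mixing proportion collapses below 1e-4 or a noise scale hits the floor
with G > 1. All randomness flows from the single `ModelSpec.seed`.

**Identifiability conventions.** Groups are reordered by descending `π`
(stable on ties); modal assignment breaks posterior ties at the lowest
group index. A scalar `orders` request is capped per indicator at
(number of observed time points − 1), so "maximal orders" means cubic for
the two fully observed indicators and quadratic for the four observed at
three censuses. Parameter count is `(G−1) + Σ_gk (q_gk + 1) + #σ`.

## Model selection

BIC is `logL − ½·p·ln n` and AIC `logL − p` (reported as negative numbers;
larger is better). Because the effective sample size of an areal panel is
ambiguous, BIC is emitted under both conventions — `bic_obs` with n = the
count of non-missing cells (the headline variant) and `bic_subjects` with
n = the number of areas. Normalized entropy is
`1 − (−ΣΣ p log p)/(N log G)` (defined as 1 at G = 1); APPA is the mean
posterior among areas assigned to a group; OCC is the APPA odds over the
chance odds `π/(1−π)`, capped at 9.5e7 with a flag when APPA reaches 1;
mismatch is assigned share minus `π̂` (sums to zero by construction).
`invert_occ` recovers the group share implied by an (APPA, OCC) pair —
useful for auditing published diagnostics tables against published share
tables.

Enumeration fits each candidate G and flags an advisory elbow where the
absolute BIC improvement first drops below a user fraction (default 0.5)
of the preceding improvement. The final G is deliberately left to the
analyst: indices are combined with substantive interpretability.

**Polynomial-order adjustment.** Backward elimination per (group,
indicator): the top-order coefficient is dropped when its Wald statistic
(coefficient over its posterior-weighted least-squares standard error,
conditional on the responsibilities — a pseudo-class approximation, since
the full information matrix is out of scope) has p > α (default 0.05);
the model is refitted by warm-started EM and the procedure repeats until
all retained top terms are significant. Intercepts are never removed.
Under a flat truth these p-values are calibrated (verified empirically:
uniform null distribution), so about 5% of tests falsely retain a term —
complete reduction of every chain to order 0 is therefore not expected,
and the tests assert the calibrated reduction rate rather than perfection.
The pre/post BIC is reported, not enforced.

## Synthetic data

The generator draws group labels from `π`, adds Gaussian noise to the
polynomial group means, clips to [0, 100] (count reported), and applies
the census availability mask (two indicators at all four time points, four
absent at the first). One integer seed drives labels then noise in fixed
area-major order, so runs are bitwise reproducible.

The reference study design (`three_group_spec`) uses G = 3 with mixing
(0.2, 0.3, 0.5), linear trajectories separated by at least 10 pp across
groups everywhere on the time range, and noise SD 2 pp — a separation of
five noise SDs, chosen as the regime in which a trajectory classification
is expected to work essentially perfectly, so that recovery failures
indicate implementation defects rather than statistical ambiguity.
Recovery experiments use N = 2000 areas with 10 seeds for label/proportion
recovery and 20 seeds for enumeration over G = 1..5; estimated mixing
proportions are compared against the draw's realized group composition,
since the realized shares differ from the nominal mixing vector by
binomial sampling noise (SD ≈ 1 pp at N = 2000) that no estimator can
remove.

What the generator does **not** emulate: spatial autocorrelation, real
British geography, within-group heteroscedasticity over time, non-Gaussian
indicator distributions, and correlated indicator noise. Passing recovery
tests therefore demonstrate correctness of the estimator under its own
assumptions, not robustness to real census data pathologies.

`generate_paired_classifications` interpolates between independent uniform
labelings (association 0) and a deterministic surjection of one labelling
onto the other (association 1; identity when r = c, giving Cramér's V of
exactly 1), providing a graded fixture for the association measures.

## Indicators and interpolation

The six indicators are ratios of published counts: internal/international
in-movers over usual residents; 18–24 and 65+ in-movers over all in-movers
(not over residents); owner-occupying and social-renting in-moving
households over all in-moving households. An optional per-(area, year)
adjustment factor pre-scales the origin-address-sensitive counts
(everything except international in-movers and usual residents); the
default is no adjustment, since no adjustment formula is published.

Boundary conversion multiplies source counts by lookup weights and sums
per target; sources without weights split equally across their targets.
Weighted and weight-free rows may not be mixed within one source — the two
regimes are alternatives, not complements. Fractional converted counts are
kept (shares are scale-free), and counts are always converted **before**
ratios are formed, because areal weighting of ratios does not conserve
mass. `validate_conversion` flags areas whose worst per-column relative
discrepancy against a trusted conversion exceeds a user tolerance; the
tolerance is a free parameter because no canonical threshold exists.

## Profiling and comparison

Classify-analyse: hard modal assignment, then per-cluster attribute means
(missing values ignored), cluster shares, and one-way fixed-effects ANOVA
per attribute with p from the F distribution (df = (G−1, N−G); zero
within-cluster variance with unequal means reports F = ∞ and p at the
machine floor). Posterior-weighted means are available for analysts who
want to carry assignment uncertainty. No multiple-testing correction is
applied across attributes by default; `anova_alpha` merely annotates
significance at a chosen level.

Classification agreement uses the Pearson chi-square test of independence
(no continuity correction; empty margins dropped with a warning) and
Cramér's V `sqrt(χ²/(n·(min(r,c)−1)))`, clipped to [0, 1] against float
overshoot. Label transfer across boundary systems assigns each target area
the source label with the largest total areal weight, ties to the lowest
label — a majority rule chosen because no published rule exists for
converting fractional weights to single labels.

## Numerical notes and degenerate inputs

* All mixture arithmetic is in log space; posterior rows always sum to 1.
* Singular weighted normal equations fall back to least-squares solves.
* Empty clusters yield NaN APPA with a flag rather than an exception.
* `share_pct` and `build_panel` reject negative counts and duplicate
  (area, year) keys; component counts exceeding their totals are rejected.
* Panel values are validated to [0, 100] on construction and on CSV read
  (`float_precision="round_trip"` keeps CSV round trips bitwise exact).

## Problem sizes

The bundled experiments run at N ≤ 2000 areas, K = 6, T = 4, G ≤ 5 with
2–3 EM starts — sizes at which a full enumeration takes seconds and the
complete recovery study a few minutes on one CPU, while leaving the
statistical conclusions (recovery, enumeration preference, calibration)
unchanged from larger runs.
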