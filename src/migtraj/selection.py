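"""Model-selection diagnostics and class enumeration.

The diagnostic battery reported for every candidate group count:

* BIC and AIC on the trajectory-modelling sign convention
  (``logL - penalty``, so larger, i.e. less negative, is better).  BIC is
  computed under both sample-size conventions — the count of non-missing
  observation cells ("BIC (Obvs)") and the count of areas.
* Normalized entropy of the posterior matrix (1 = perfect separation).
* Per-group APPA (average posterior probability of assignment), OCC (odds
  of correct classification), and mismatch (hard-assigned share minus
  estimated mixing proportion).
* Smallest estimated group share.

Enumeration fits a model per candidate G and flags an advisory "elbow"
where the BIC improvement levels out; the final choice of G remains a
user decision combining indices and interpretability.  Polynomial-order
adjustment backward-eliminates non-significant top-order trajectory terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gbmt import FittedModel, ModelSpec, _design, count_parameters, fit, refit_from
from .panel import IndicatorPanel

#: Reporting cap for OCC when APPA reaches 1 (odds are infinite).
OCC_CAP = 9.5e7


def bic(logL: float, n_params: int, n: int) -> float:
    """Bayesian information criterion, ``logL - 0.5 * p * ln(n)``.

    Trajectory-model convention: reported on the log-likelihood scale as a
    negative number, larger (closer to zero) meaning better fit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(logL - 0.5 * n_params * np.log(n))


def aic(logL: float, n_params: int) -> float:
    """Akaike information criterion on the same sign convention as :func:`bic`."""
    return float(logL - n_params)


def entropy(posteriors: np.ndarray) -> float:
    """Normalized classification entropy in [0, 1]; 1 means crisp assignment.

    ``1 - (-sum p log p) / (N log G)`` with ``p log p = 0`` at ``p = 0``;
    defined as 1 for a single group.
    """
    p = np.asarray(posteriors, dtype=float)
    n, g = p.shape
    if g == 1:
        return 1.0
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ent = -plogp.sum()
    return float(min(1.0, max(0.0, 1.0 - ent / (n * np.log(g)))))


def appa(posteriors: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average posterior probability of assignment per group (NaN if empty).

    ``labels`` are 1-based modal assignments.
    """
    p = np.asarray(posteriors, dtype=float)
    labels = np.asarray(labels, dtype=int)
    g = p.shape[1]
    out = np.full(g, np.nan)
    for j in range(g):
        members = labels == j + 1
        if members.any():
            out[j] = p[members, j].mean()
    return out


def occ(appa_j: float, pi_j: float) -> float:
    """Odds of correct classification: assignment odds over chance odds.

    ``[appa/(1-appa)] / [pi/(1-pi)]``; capped at :data:`OCC_CAP` when the
    assignment odds are infinite (APPA of exactly 1).
    """
    if not 0 < pi_j < 1:
        raise ValueError("pi_j must lie in (0, 1)")
    if not 0 < appa_j <= 1:
        raise ValueError("appa_j must lie in (0, 1]")
    chance_odds = pi_j / (1.0 - pi_j)
    if appa_j >= 1.0:
        return OCC_CAP
    return float((appa_j / (1.0 - appa_j)) / chance_odds)


def invert_occ(appa_j: float, occ_j: float) -> float:
    """Group proportion implied by an (APPA, OCC) pair — the inverse of :func:`occ`.

    Solving OCC = [appa/(1-appa)] / [pi/(1-pi)] for pi gives
    ``x = [appa/(1-appa)] / OCC`` and ``pi = x / (1 + x)``.  Applying this to
    a published diagnostics table recovers the group shares it implies.
    """
    if not 0 < appa_j < 1:
        raise ValueError("appa_j must lie in (0, 1)")
    if occ_j <= 0:
        raise ValueError("occ_j must be > 0")
    x = (appa_j / (1.0 - appa_j)) / occ_j
    return float(x / (1.0 + x))


def mismatch(labels: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Hard-assigned share minus estimated mixing proportion, per group."""
    labels = np.asarray(labels, dtype=int)
    pi = np.asarray(pi, dtype=float)
    n = len(labels)
    assigned = np.array([(labels == j + 1).sum() / n for j in range(len(pi))])
    return assigned - pi


@dataclass
class FitDiagnostics:
    """One diagnostics row for a fitted model with G groups."""

    n_groups: int
    bic_obs: float
    bic_subjects: float
    aic: float
    entropy: float
    appa: np.ndarray
    occ: np.ndarray
    occ_capped: np.ndarray
    mismatch: np.ndarray
    smallest_group_pct: float
    logL: float
    n_params: int
    converged: bool

    def to_row(self) -> dict:
        return {
            "G": self.n_groups,
            "bic_obs": self.bic_obs,
            "bic_subjects": self.bic_subjects,
            "aic": self.aic,
            "entropy": self.entropy,
            "appa": "|".join(f"{v:.7g}" for v in self.appa),
            "occ": "|".join(f"{v:.7g}" for v in self.occ),
            "mismatch": "|".join(f"{v:.7g}" for v in self.mismatch),
            "smallest_group_pct": self.smallest_group_pct,
            "logL": self.logL,
            "n_params": self.n_params,
            "converged": self.converged,
        }


def diagnose(model: FittedModel) -> FitDiagnostics:
    """Compute the full diagnostic battery from a fitted model."""
    appa_vec = appa(model.posteriors, model.labels)
    occ_vec = np.full(model.n_groups, np.nan)
    capped = np.zeros(model.n_groups, dtype=bool)
    for j in range(model.n_groups):
        if np.isnan(appa_vec[j]) or not 0 < model.pi[j] < 1:
            continue
        occ_vec[j] = occ(appa_vec[j], model.pi[j])
        capped[j] = appa_vec[j] >= 1.0
    return FitDiagnostics(
        n_groups=model.n_groups,
        bic_obs=bic(model.logL, model.n_params, model.n_obs),
        bic_subjects=bic(model.logL, model.n_params, model.n_areas),
        aic=aic(model.logL, model.n_params),
        entropy=entropy(model.posteriors),
        appa=appa_vec,
        occ=occ_vec,
        occ_capped=capped,
        mismatch=mismatch(model.labels, model.pi),
        smallest_group_pct=float(100.0 * model.pi.min()),
        logL=model.logL,
        n_params=model.n_params,
        converged=model.converged,
    )


@dataclass
class EnumerationTable:
    """Diagnostics rows over a range of candidate group counts."""

    rows: list[FitDiagnostics]
    models: dict[int, FittedModel]
    errors: dict[int, str]
    elbow_G: int | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_row() for r in self.rows])
        if self.elbow_G is not None and len(df):
            df["elbow"] = df["G"] == self.elbow_G
        return df

    def best_by(self, criterion: str = "bic_obs") -> int:
        """G with the largest (least negative) value of the criterion."""
        vals = {r.n_groups: getattr(r, criterion) for r in self.rows}
        return max(vals, key=vals.get)


def enumerate_models(
    panel: IndicatorPanel,
    G_values,
    template: ModelSpec | None = None,
    elbow_fraction: float = 0.5,
    **spec_kwargs,
) -> EnumerationTable:
    """Fit one model per candidate group count and tabulate diagnostics.

    ``template`` supplies the shared fit configuration (orders, variance
    mode, tolerances, seed); its group count is overridden per candidate.
    Fit failures are recorded per row and enumeration continues.  The
    advisory elbow is the first G at which the absolute BIC improvement
    falls below ``elbow_fraction`` of the preceding improvement.
    """
    G_values = sorted(set(int(g) for g in G_values))
    if not G_values:
        raise ValueError("G_values must be nonempty")
    base = template if template is not None else ModelSpec(n_groups=1, **spec_kwargs)
    rows: list[FitDiagnostics] = []
    models: dict[int, FittedModel] = {}
    errors: dict[int, str] = {}
    for g in G_values:
        spec = ModelSpec(
            n_groups=g,
            orders=base.orders,
            variance_mode=base.variance_mode,
            max_iter=base.max_iter,
            tol=base.tol,
            n_starts=base.n_starts,
            seed=base.seed,
        )
        try:
            model = fit(panel, spec)
        except Exception as exc:  # keep enumerating; record the failure
            errors[g] = f"{type(exc).__name__}: {exc}"
            continue
        models[g] = model
        rows.append(diagnose(model))
    elbow = None
    if len(rows) >= 3:
        gs = [r.n_groups for r in rows]
        bics = [r.bic_obs for r in rows]
        deltas = np.abs(np.diff(bics))
        for i in range(1, len(deltas)):
            if deltas[i] < elbow_fraction * deltas[i - 1]:
                elbow = gs[i + 1]
                break
    return EnumerationTable(rows=rows, models=models, errors=errors, elbow_G=elbow)


def _top_term_pvalues(panel: IndicatorPanel, model: FittedModel) -> np.ndarray:
    """Wald p-values of each (g, k) highest-order coefficient (NaN at order 0).

    Standard errors are posterior-weighted least-squares errors conditional
    on the E-step responsibilities (pseudo-class approximation): for group g
    and indicator k, ``cov = sigma_k^2 (X' W X)^{-1}`` with W the total
    posterior weight at each observed time.
    """
    g, k = model.orders.shape
    pvals = np.full((g, k), np.nan)
    y0 = np.where(panel.mask, panel.values, 0.0)
    for kk in range(k):
        m_k = panel.mask[:, kk, :].astype(float)
        w_gt = model.posteriors.T @ m_k  # (G, T)
        sigma_gk = model.sigma if model.sigma.ndim == 2 else np.tile(model.sigma, (g, 1))
        for gg in range(g):
            order = int(model.orders[gg, kk])
            if order < 1:
                continue
            x = _design(panel.times, order)
            a_mat = x.T @ (w_gt[gg][:, None] * x)
            try:
                cov = sigma_gk[gg, kk] ** 2 * np.linalg.inv(a_mat)
            except np.linalg.LinAlgError:
                continue
            se = np.sqrt(max(cov[order, order], 1e-300))
            z = model.beta[gg, kk, order] / se
            pvals[gg, kk] = 2.0 * stats.norm.sf(abs(z))
    return pvals


def adjust_polynomial_orders(
    panel: IndicatorPanel,
    model: FittedModel,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    max_rounds: int = 20,
) -> FittedModel:
    """Backward-eliminate non-significant top-order trajectory terms.

    In each round, every (group, indicator) whose highest-order coefficient
    has Wald p > ``alpha`` loses that term; the model is then refitted by
    warm-started EM, and the procedure repeats until every retained
    top-order term is significant.  Intercepts are never removed.  The
    refitted model carries an ``adjustment_report`` attribute with the
    pre/post observation-count BIC (a better post-adjustment BIC is
    reported, not enforced).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if spec is None:
        spec = ModelSpec(n_groups=model.n_groups, orders=model.orders, variance_mode=model.variance_mode)
    pre_bic = bic(model.logL, model.n_params, model.n_obs)
    current = model
    orders = model.orders.copy()
    for _ in range(max_rounds):
        pvals = _top_term_pvalues(panel, current)
        droppable = (orders >= 1) & ~np.isnan(pvals) & (pvals > alpha)
        if not droppable.any():
            break
        orders = np.where(droppable, orders - 1, orders)
        current = refit_from(panel, current, orders, spec)
    post_bic = bic(current.logL, current.n_params, current.n_obs)
    current.adjustment_report = {
        "pre_bic_obs": pre_bic,
        "post_bic_obs": post_bic,
        "pre_n_params": model.n_params,
        "post_n_params": current.n_params,
        "orders": orders.tolist(),
    }
    return current
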