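"""Group-based multi-trajectory mixture model fitted by EM.

The model: each area i belongs to one of G latent groups with prior
probabilities pi_g.  Conditional on group g, every observed cell
y[i, k, t] is independent Gaussian with mean mu_gk(t) — a polynomial in
coded time of per-(group, indicator) order — and scale sigma (one per
indicator, optionally per group and indicator).  Missing cells contribute
nothing to the likelihood (missing at random), which is how the absent
first-census indicators are handled.

Fitting alternates an exact E-step (posterior memberships in log space)
with closed-form M-steps: mixing proportions are mean posteriors,
trajectory coefficients come from posterior-weighted least squares of the
observations on the time polynomial, and noise scales from
posterior-weighted residuals.  Multi-start initialisation uses k-means on
missing-aware time-averaged indicator profiles; groups are canonicalised
by descending mixing proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .panel import IndicatorPanel

LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA_FLOOR = 1e-6  # pp; lower bound so degenerate zero-noise fits stay finite
COLLAPSE_PI = 1e-4


@dataclass
class ModelSpec:
    """Fit configuration: group count, polynomial orders, EM controls.

    ``orders`` is a single integer applied to every (group, indicator) or a
    ``(G, K)`` integer array; every order must lie in ``[0, T-1]``.
    ``variance_mode`` is ``"shared"`` (one sigma per indicator, the
    trajectory-software default) or ``"by_group"``.
    """

    n_groups: int
    orders: int | np.ndarray = 3
    variance_mode: str = "shared"
    max_iter: int = 500
    tol: float = 1e-8
    n_starts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.variance_mode not in ("shared", "by_group"):
            raise ValueError("variance_mode must be 'shared' or 'by_group'")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def order_matrix(self, n_indicators: int, n_timepoints: int) -> np.ndarray:
        orders = np.asarray(self.orders)
        if orders.ndim == 0:
            orders = np.full((self.n_groups, n_indicators), int(orders))
        orders = orders.astype(int)
        if orders.shape != (self.n_groups, n_indicators):
            raise ValueError("orders must be scalar or shaped (G, K)")
        if (orders < 0).any() or (orders > n_timepoints - 1).any():
            raise ValueError("orders must lie in [0, T-1]")
        return orders


@dataclass
class FittedModel:
    """Estimated mixture: parameters, posteriors, assignments, fit metadata.

    ``beta`` has shape ``(G, K, max_order+1)`` with coefficients above each
    (g, k) order fixed at zero; ``labels`` are 1-based modal assignments
    after canonical reordering by descending ``pi``.
    """

    pi: np.ndarray
    beta: np.ndarray
    orders: np.ndarray
    sigma: np.ndarray
    variance_mode: str
    logL: float
    n_params: int
    posteriors: np.ndarray
    labels: np.ndarray
    converged: bool
    n_obs: int
    n_iter: int
    logL_path: np.ndarray
    area_ids: np.ndarray
    times: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.pi)

    @property
    def n_areas(self) -> int:
        return self.posteriors.shape[0]

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "beta": self.beta.tolist(),
            "orders": self.orders.tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
            "variance_mode": self.variance_mode,
            "logL": float(self.logL),
            "n_params": int(self.n_params),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_iter": int(self.n_iter),
            "times": self.times.tolist(),
        }


# -- likelihood pieces -----------------------------------------------------


def _design(times: np.ndarray, order: int) -> np.ndarray:
    """Polynomial design matrix (T, order+1): columns 1, t, t^2, ..."""
    return times[:, None] ** np.arange(order + 1)[None, :]


def _means(beta: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Trajectory means (G, K, T) from padded coefficients (G, K, P)."""
    powers = times[None, :] ** np.arange(beta.shape[2])[:, None]  # (P, T)
    return np.einsum("gkp,pt->gkt", beta, powers)


def _component_loglik(
    panel_values: np.ndarray, mask: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Per-area, per-group Gaussian log likelihood over observed cells (N, G)."""
    y = np.where(mask, panel_values, 0.0)[:, None, :, :]  # (N, 1, K, T)
    m = mask[:, None, :, :]
    if sigma.ndim == 1:
        s = sigma[None, None, :, None]
    else:  # (G, K)
        s = sigma[None, :, :, None]
    z = (y - mu[None]) / s
    cell = -0.5 * (z * z) - np.log(s) - 0.5 * LOG_2PI
    return np.where(m, cell, 0.0).sum(axis=(2, 3))


def _validate_sigma(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if not np.isfinite(sigma).all() or (sigma <= 0).any():
        raise ValueError("sigma must be finite and > 0")
    return sigma


def log_likelihood(panel: IndicatorPanel, pi, beta, sigma) -> float:
    """Observed-data mixture log likelihood of a panel under given parameters.

    ``sum_i log sum_g pi_g * prod_observed N(y_ikt | mu_gk(t), sigma)``.
    """
    pi = np.asarray(pi, dtype=float)
    beta = np.asarray(beta, dtype=float)
    sigma = _validate_sigma(sigma)
    if not np.isfinite(beta).all() or not np.isfinite(pi).all():
        raise ValueError("parameters must be finite")
    mu = _means(beta, panel.times)
    comp = _component_loglik(panel.values, panel.mask, mu, sigma)
    with np.errstate(divide="ignore"):
        return float(logsumexp(comp + np.log(pi)[None, :], axis=1).sum())


def posterior_memberships(panel: IndicatorPanel, pi, beta, sigma) -> np.ndarray:
    """Posterior group membership probabilities, one row per area (N, G).

    Computed in log space, so near-zero group likelihoods underflow
    gracefully instead of producing 0/0.
    """
    pi = np.asarray(pi, dtype=float)
    beta = np.asarray(beta, dtype=float)
    sigma = _validate_sigma(sigma)
    if not np.isfinite(beta).all() or not np.isfinite(pi).all():
        raise ValueError("parameters must be finite")
    mu = _means(beta, panel.times)
    comp = _component_loglik(panel.values, panel.mask, mu, sigma)
    with np.errstate(divide="ignore"):
        logp = comp + np.log(pi)[None, :]
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def trajectory_means(model: FittedModel, group: int, indicator: int) -> np.ndarray:
    """Fitted mean trajectory of one group for one indicator over the panel times."""
    return _means(model.beta[[group]], model.times)[0, indicator]


def count_parameters(orders: np.ndarray, variance_mode: str) -> int:
    """Free parameters: (G-1) mixing + trajectory coefficients + noise scales."""
    g, k = orders.shape
    n_sigma = k if variance_mode == "shared" else g * k
    return (g - 1) + int((orders + 1).sum()) + n_sigma


# -- EM --------------------------------------------------------------------


def _m_step_beta(
    values: np.ndarray, mask: np.ndarray, resp: np.ndarray, orders: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Posterior-weighted least-squares update of trajectory coefficients."""
    n, k, t = values.shape
    g = resp.shape[1]
    p_max = int(orders.max()) + 1
    beta = np.zeros((g, k, p_max))
    y0 = np.where(mask, values, 0.0)
    for kk in range(k):
        m_k = mask[:, kk, :].astype(float)  # (N, T)
        w_gt = resp.T @ m_k  # (G, T) total weight at each time
        b_gt = resp.T @ (y0[:, kk, :])  # (G, T) weighted y sums
        for gg in range(g):
            x = _design(times, int(orders[gg, kk]))  # (T, P)
            a_mat = x.T @ (w_gt[gg][:, None] * x)
            b_vec = x.T @ b_gt[gg]
            try:
                coef = np.linalg.solve(a_mat, b_vec)
            except np.linalg.LinAlgError:
                coef = np.linalg.lstsq(a_mat, b_vec, rcond=None)[0]
            beta[gg, kk, : len(coef)] = coef
    return beta


def _m_step_sigma(
    values: np.ndarray, mask: np.ndarray, resp: np.ndarray, mu: np.ndarray, variance_mode: str
) -> np.ndarray:
    y = np.where(mask, values, 0.0)[:, None, :, :]
    m = mask[:, None, :, :]
    sq = np.where(m, (y - mu[None]) ** 2, 0.0)  # (N, G, K, T)
    wsq = np.einsum("ng,ngkt->gk", resp, sq)  # (G, K)
    wobs = np.einsum("ng,nkt->gk", resp, mask.astype(float))
    if variance_mode == "shared":
        var = wsq.sum(axis=0) / np.maximum(wobs.sum(axis=0), 1e-12)  # (K,)
    else:
        var = wsq / np.maximum(wobs, 1e-12)  # (G, K)
    return np.maximum(np.sqrt(var), SIGMA_FLOOR)


def _init_responsibilities(panel: IndicatorPanel, g: int, rng: np.random.Generator, start: int) -> np.ndarray:
    """K-means starting partition on missing-aware time-averaged profiles."""
    n = panel.n_areas
    if g == 1:
        return np.ones((n, 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feats = np.nanmean(panel.values, axis=2)  # (N, K)
    col_mean = np.nanmean(feats, axis=0)
    feats = np.where(np.isfinite(feats), feats, np.nan_to_num(col_mean))
    if start == 0:
        labels = KMeans(n_clusters=g, n_init=5, random_state=int(rng.integers(2**31))).fit_predict(feats)
    else:
        # jittered restart: perturb features before clustering
        scale = feats.std(axis=0, ddof=0) + 1e-9
        jit = feats + rng.standard_normal(feats.shape) * scale * 0.5
        labels = KMeans(n_clusters=g, n_init=1, random_state=int(rng.integers(2**31))).fit_predict(jit)
    resp = np.full((n, g), 0.05 / max(g - 1, 1))
    resp[np.arange(n), labels] = 0.95
    return resp / resp.sum(axis=1, keepdims=True)


def _em_run(
    panel: IndicatorPanel,
    orders: np.ndarray,
    variance_mode: str,
    resp: np.ndarray,
    max_iter: int,
    tol: float,
) -> dict:
    """One EM run from an initial responsibility matrix; returns raw state."""
    values, mask, times = panel.values, panel.mask, panel.times
    g = resp.shape[1]
    logl_path: list[float] = []
    prev = -np.inf
    converged = False
    pi = beta = sigma = None
    for it in range(max_iter):
        pi = np.maximum(resp.mean(axis=0), 1e-300)
        pi = pi / pi.sum()
        beta = _m_step_beta(values, mask, resp, orders, times)
        mu = _means(beta, times)
        sigma = _m_step_sigma(values, mask, resp, mu, variance_mode)
        comp = _component_loglik(values, mask, mu, sigma)
        logp = comp + np.log(pi)[None, :]
        norm = logsumexp(logp, axis=1, keepdims=True)
        logl = float(norm.sum())
        resp = np.exp(logp - norm)
        logl_path.append(logl)
        if prev > -np.inf and (logl - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = logl
    collapsed = bool((pi < COLLAPSE_PI).any()) or bool((np.asarray(sigma) <= SIGMA_FLOOR).any() and g > 1)
    return {
        "pi": pi,
        "beta": beta,
        "sigma": sigma,
        "resp": resp,
        "logL": logl_path[-1],
        "logL_path": np.array(logl_path),
        "converged": converged,
        "collapsed": collapsed,
        "n_iter": len(logl_path),
    }


def _canonicalize(state: dict, orders: np.ndarray) -> tuple[dict, np.ndarray]:
    """Reorder groups by descending mixing proportion (stable on ties)."""
    order = np.argsort(-state["pi"], kind="stable")
    state = dict(state)
    state["pi"] = state["pi"][order]
    state["beta"] = state["beta"][order]
    state["resp"] = state["resp"][:, order]
    if np.asarray(state["sigma"]).ndim == 2:
        state["sigma"] = state["sigma"][order]
    return state, orders[order]


def fit(panel: IndicatorPanel, spec: ModelSpec) -> FittedModel:
    """Maximum-likelihood fit of the G-group multi-trajectory model.

    Runs EM from ``n_starts`` initialisations (k-means, then jittered
    restarts) and keeps the best non-degenerate run by log likelihood; a run
    that collapses a group (mixing proportion below 1e-4) or drives a noise
    scale to the floor is treated as degenerate unless every start does.
    Raises ``ValueError`` when the panel cannot identify the requested
    polynomial orders.
    """
    orders = spec.order_matrix(panel.n_indicators, panel.n_timepoints)
    if panel.n_areas < spec.n_groups:
        raise ValueError("need at least as many areas as groups")
    obs_times = panel.mask.any(axis=0).sum(axis=1)  # (K,) distinct observed times
    if np.isscalar(spec.orders) or np.asarray(spec.orders).ndim == 0:
        # a scalar order means "up to this order", capped by what each
        # indicator's availability can identify (observed times - 1)
        orders = np.minimum(orders, (obs_times - 1)[None, :])
    needed = orders.max(axis=0) + 1
    if (obs_times < needed).any():
        bad = [panel.indicators[j] for j in np.where(obs_times < needed)[0]]
        raise ValueError(f"not enough observed time points for requested order: {bad}")

    rng = np.random.default_rng(spec.seed)
    best = None
    best_any = None
    for start in range(spec.n_starts):
        resp0 = _init_responsibilities(panel, spec.n_groups, rng, start)
        state = _em_run(panel, orders, spec.variance_mode, resp0, spec.max_iter, spec.tol)
        if best_any is None or state["logL"] > best_any["logL"]:
            best_any = state
        if not state["collapsed"] and (best is None or state["logL"] > best["logL"]):
            best = state
        if spec.n_groups == 1:
            break
    if best is None:
        warnings.warn("all EM starts degenerate or non-converged; returning best available")
        best = best_any
    if not best["converged"]:
        warnings.warn("EM did not converge within max_iter")
    state, orders_c = _canonicalize(best, orders)
    labels = state["resp"].argmax(axis=1) + 1  # argmax breaks ties at lowest index
    return FittedModel(
        pi=state["pi"],
        beta=state["beta"],
        orders=orders_c,
        sigma=np.asarray(state["sigma"]),
        variance_mode=spec.variance_mode,
        logL=state["logL"],
        n_params=count_parameters(orders_c, spec.variance_mode),
        posteriors=state["resp"],
        labels=labels,
        converged=state["converged"],
        n_obs=panel.n_obs,
        n_iter=state["n_iter"],
        logL_path=state["logL_path"],
        area_ids=panel.area_ids,
        times=panel.times,
    )


def refit_from(panel: IndicatorPanel, model: FittedModel, orders: np.ndarray, spec: ModelSpec) -> FittedModel:
    """Warm-start EM from an existing model's posteriors with new orders."""
    orders = np.asarray(orders, dtype=int)
    state = _em_run(panel, orders, spec.variance_mode, model.posteriors, spec.max_iter, spec.tol)
    state, orders_c = _canonicalize(state, orders)
    labels = state["resp"].argmax(axis=1) + 1
    return FittedModel(
        pi=state["pi"],
        beta=state["beta"],
        orders=orders_c,
        sigma=np.asarray(state["sigma"]),
        variance_mode=spec.variance_mode,
        logL=state["logL"],
        n_params=count_parameters(orders_c, spec.variance_mode),
        posteriors=state["resp"],
        labels=labels,
        converged=state["converged"],
        n_obs=panel.n_obs,
        n_iter=state["n_iter"],
        logL_path=state["logL_path"],
        area_ids=panel.area_ids,
        times=panel.times,
    )
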