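import numpy as np
import pytest
from scipy.stats import norm

import migtraj as m
from migtraj.gbmt import SIGMA_FLOOR, count_parameters

from conftest import random_small_panel


# -- independent oracle: unvectorized mixture likelihood --------------------


def _brute_force_group_logliks(panel, pi, beta, sigma, i):
    """Scalar log p(area i, group g) accumulated cell by cell."""
    import math

    sigma = np.asarray(sigma)
    out = []
    for gg in range(len(pi)):
        logp = math.log(pi[gg]) if pi[gg] > 0 else -math.inf
        for kk in range(panel.n_indicators):
            s = sigma[kk] if sigma.ndim == 1 else sigma[gg, kk]
            for tt in range(panel.n_timepoints):
                if panel.mask[i, kk, tt]:
                    mu = sum(beta[gg, kk, j] * tt**j for j in range(beta.shape[2]))
                    logp += norm.logpdf(panel.values[i, kk, tt], mu, s)
        out.append(logp)
    return out


def brute_force_loglik(panel, pi, beta, sigma):
    """Loop over areas, groups and cells with scalar normal log densities."""
    import math

    total = 0.0
    for i in range(panel.n_areas):
        logps = _brute_force_group_logliks(panel, pi, beta, sigma, i)
        peak = max(logps)
        total += peak + math.log(sum(math.exp(lp - peak) for lp in logps))
    return total


def brute_force_posteriors(panel, pi, beta, sigma):
    import math

    n = panel.n_areas
    g = len(pi)
    out = np.zeros((n, g))
    for i in range(n):
        logps = _brute_force_group_logliks(panel, pi, beta, sigma, i)
        peak = max(logps)
        weights = [math.exp(lp - peak) for lp in logps]
        out[i] = np.array(weights) / sum(weights)
    return out


def random_params(rng, g, k, p_max=2):
    pi = rng.dirichlet(np.ones(g) * 3)
    beta = rng.uniform(10, 90, size=(g, k, 1))
    if p_max > 1:
        slopes = rng.uniform(-5, 5, size=(g, k, p_max - 1))
        beta = np.concatenate([beta, slopes], axis=2)
    sigma = rng.uniform(2, 15, size=k)
    return pi, beta, sigma


class TestLogLikelihood:
    def test_single_standard_normal_cell_at_mode(self):
        panel = m.IndicatorPanel(
            values=np.array([[[50.0]]]),
            mask=np.ones((1, 1, 1), bool),
            area_ids=np.array(["A"]),
            years=np.array([2001]),
            indicators=("indicator_1",),
        )
        ll = m.log_likelihood(panel, pi=[1.0], beta=np.array([[[50.0]]]), sigma=[1.0])
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g, k, t = rng.integers(1, 4), rng.integers(1, 3), rng.integers(2, 4)
            panel = random_small_panel(rng, n=int(rng.integers(1, 6)), k=int(k), t=int(t))
            pi, beta, sigma = random_params(rng, int(g), int(k))
            assert m.log_likelihood(panel, pi, beta, sigma) == pytest.approx(
                brute_force_loglik(panel, pi, beta, sigma), abs=1e-10
            )

    def test_fully_missing_indicator_is_neutral(self):
        rng = np.random.default_rng(3)
        panel = random_small_panel(rng, n=4, k=2, t=3)
        pi, beta, sigma = random_params(rng, 2, 2)
        base = m.log_likelihood(panel, pi, beta, sigma)
        # append an indicator with no observations at all
        values = np.concatenate([panel.values, np.full((4, 1, 3), np.nan)], axis=1)
        mask = np.concatenate([panel.mask, np.zeros((4, 1, 3), bool)], axis=1)
        bigger = m.IndicatorPanel(
            values, mask, panel.area_ids, panel.years, panel.indicators + ("extra",)
        )
        beta2 = np.concatenate([beta, np.zeros((2, 1, beta.shape[2]))], axis=1)
        sigma2 = np.append(sigma, 5.0)
        assert m.log_likelihood(bigger, pi, beta2, sigma2) == pytest.approx(base, abs=1e-10)

    def test_rejects_nonpositive_sigma(self):
        rng = np.random.default_rng(1)
        panel = random_small_panel(rng, n=2, k=1, t=2)
        with pytest.raises(ValueError):
            m.log_likelihood(panel, [1.0], np.zeros((1, 1, 1)), [0.0])

    def test_invariant_to_area_order_and_group_relabeling(self):
        rng = np.random.default_rng(8)
        panel = random_small_panel(rng, n=6, k=2, t=3)
        pi, beta, sigma = random_params(rng, 3, 2)
        base = m.log_likelihood(panel, pi, beta, sigma)
        perm_areas = rng.permutation(6)
        shuffled = m.IndicatorPanel(
            panel.values[perm_areas], panel.mask[perm_areas],
            panel.area_ids[perm_areas], panel.years, panel.indicators,
        )
        assert m.log_likelihood(shuffled, pi, beta, sigma) == pytest.approx(base, abs=1e-10)
        perm_g = rng.permutation(3)
        assert m.log_likelihood(panel, pi[perm_g], beta[perm_g], sigma) == pytest.approx(
            base, abs=1e-10
        )


class TestPosteriorMemberships:
    def test_identical_groups_split_evenly(self):
        rng = np.random.default_rng(5)
        panel = random_small_panel(rng, n=4, k=2, t=3)
        beta = np.tile(np.array([[[50.0, 1.0], [30.0, -1.0]]]), (2, 1, 1))
        post = m.posterior_memberships(panel, [0.5, 0.5], beta, [5.0, 5.0])
        assert np.allclose(post, 0.5, atol=1e-12)

    def test_degenerate_prior(self):
        rng = np.random.default_rng(6)
        panel = random_small_panel(rng, n=4, k=2, t=3)
        pi, beta, sigma = random_params(rng, 2, 2)
        post = m.posterior_memberships(panel, [1.0, 0.0], beta, sigma)
        assert np.allclose(post[:, 0], 1.0)

    def test_matches_brute_force_bayes(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            panel = random_small_panel(rng, n=int(rng.integers(2, 6)), k=2, t=3)
            pi, beta, sigma = random_params(rng, 3, 2)
            np.testing.assert_allclose(
                m.posterior_memberships(panel, pi, beta, sigma),
                brute_force_posteriors(panel, pi, beta, sigma),
                atol=1e-10,
            )

    def test_rows_sum_to_one_even_for_outlying_areas(self):
        # far-off observations underflow per-group likelihoods; log-space
        # computation must still give normalized rows
        values = np.array([[[0.0]], [[100.0]]])
        panel = m.IndicatorPanel(
            values, np.ones((2, 1, 1), bool), np.array(["A", "B"]),
            np.array([2001]), ("indicator_1",),
        )
        beta = np.array([[[99.9]], [[99.8]]])
        post = m.posterior_memberships(panel, [0.5, 0.5], beta, [0.01])
        assert np.allclose(post.sum(axis=1), 1.0)
        assert np.isfinite(post).all()


class TestFit:
    def test_zero_noise_one_group_recovers_line(self):
        t = np.arange(4.0)
        line = 20.0 + 3.0 * t
        values = np.tile(line, (5, 1, 1))  # (5, 1, 4)
        panel = m.IndicatorPanel(
            values, np.ones((5, 1, 4), bool), np.array([f"A{i}" for i in range(5)]),
            np.array([1981, 1991, 2001, 2011]), ("indicator_1",),
        )
        model = m.fit(panel, m.ModelSpec(n_groups=1, orders=1, seed=0, n_starts=1))
        assert model.beta[0, 0, 0] == pytest.approx(20.0, abs=1e-6)
        assert model.beta[0, 0, 1] == pytest.approx(3.0, abs=1e-6)
        assert model.sigma[0] == pytest.approx(SIGMA_FLOOR)

    def test_one_group_reduces_to_least_squares(self):
        rng = np.random.default_rng(21)
        panel = random_small_panel(rng, n=30, k=2, t=4, with_missing=False)
        model = m.fit(panel, m.ModelSpec(n_groups=1, orders=1, seed=0, n_starts=1))
        x = np.column_stack([np.ones(4), np.arange(4.0)])
        for k in range(2):
            y = panel.values[:, k, :]  # (N, T)
            design = np.tile(x, (30, 1))
            coef, *_ = np.linalg.lstsq(design, y.ravel(), rcond=None)
            np.testing.assert_allclose(model.beta[0, k, :2], coef, atol=1e-8)

    def test_recovers_well_separated_groups(self, three_group_sim, fitted_three):
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(three_group_sim.true_labels, fitted_three.labels)
        assert ari >= 0.95
        # pi should match this draw's empirical group shares (the nominal
        # proportions carry ~2pp binomial sampling error at N=500)
        empirical = np.sort(np.bincount(three_group_sim.true_labels)[1:] / 500)[::-1]
        assert np.abs(fitted_three.pi - empirical).max() <= 0.01

    def test_em_loglik_nondecreasing(self, fitted_three):
        path = fitted_three.logL_path
        assert np.all(np.diff(path) >= -1e-7 * (np.abs(path[:-1]) + 1))

    def test_em_monotone_on_fuzzed_panels(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            panel = random_small_panel(rng, n=40, k=3, t=4)
            model = m.fit(panel, m.ModelSpec(n_groups=2, orders=2, seed=1, n_starts=1, max_iter=60))
            path = model.logL_path
            assert np.all(np.diff(path) >= -1e-7 * (np.abs(path[:-1]) + 1))

    def test_posterior_rows_sum_to_one(self, fitted_three):
        assert np.allclose(fitted_three.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_groups_canonicalized_by_descending_pi(self, fitted_three):
        assert np.all(np.diff(fitted_three.pi) <= 1e-12)

    def test_n_params_accounting(self, fitted_three):
        # (G-1) mixing + per-(g,k) coefficients + shared sigmas
        expected = 2 + int((fitted_three.orders + 1).sum()) + 6
        assert fitted_three.n_params == expected
        assert count_parameters(np.array([[1, 2], [0, 3]]), "by_group") == 1 + (2 + 3 + 1 + 4) + 4

    def test_needs_enough_areas(self):
        rng = np.random.default_rng(2)
        panel = random_small_panel(rng, n=2, k=2, t=3)
        with pytest.raises(ValueError):
            m.fit(panel, m.ModelSpec(n_groups=5))


class TestTrajectoryMeans:
    def test_constant_and_line(self, three_group_sim):
        panel = three_group_sim.panel
        model = m.fit(panel, m.ModelSpec(n_groups=1, orders=0, seed=0, n_starts=1))
        mu = m.trajectory_means(model, 0, 0)
        assert np.allclose(mu, mu[0])
        beta = np.zeros((1, 1, 2))
        beta[0, 0] = [7.0, 2.0]
        lin = m.FittedModel(
            pi=np.array([1.0]), beta=beta, orders=np.array([[1]]), sigma=np.array([1.0]),
            variance_mode="shared", logL=0.0, n_params=3,
            posteriors=np.ones((1, 1)), labels=np.array([1]), converged=True,
            n_obs=4, n_iter=1, logL_path=np.zeros(1),
            area_ids=np.array(["A"]), times=np.arange(4.0),
        )
        assert np.allclose(m.trajectory_means(lin, 0, 0), [7.0, 9.0, 11.0, 13.0])

    def test_matches_posterior_weighted_empirical_means(self, three_group_sim, fitted_three):
        panel = three_group_sim.panel
        post = fitted_three.posteriors
        for g in range(3):
            w = post[:, g]
            for k in range(6):
                emp = np.nansum(w[:, None] * np.nan_to_num(panel.values[:, k, :]), axis=0) / (
                    w @ panel.mask[:, k, :]
                )
                fit_mu = m.trajectory_means(fitted_three, g, k)
                obs_t = panel.mask[:, k, :].any(axis=0)
                # agreement within the 2pp noise scale on observed times
                assert np.abs(emp[obs_t] - fit_mu[obs_t]).max() < 1.0
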