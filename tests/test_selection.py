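import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import migtraj as m
from migtraj.selection import OCC_CAP

# Published six-group diagnostics used for internal-consistency checks:
# (APPA, OCC) per group of the chosen model.
SIX_GROUP_DIAGNOSTICS = [
    (0.9845982, 37.22547),
    (0.9643457, 100.0744),
    (0.9475669, 150.0891),
    (0.9778698, 2300.956),
    (0.9862717, 2932.045),
    (0.9999979, 95000000.0),
]


class TestInformationCriteria:
    def test_bic_closed_form(self):
        assert m.bic(-100.0, 3, 100) == pytest.approx(-100 - 1.5 * np.log(100), abs=1e-4)
        assert m.bic(-100.0, 3, 100) == pytest.approx(-106.9078, abs=1e-4)

    def test_no_penalty_without_parameters(self):
        assert m.bic(-55.5, 0, 1000) == -55.5
        assert m.aic(0.0, 0) == 0.0

    def test_aic_closed_form(self):
        assert m.aic(-100.0, 3) == -103.0

    @given(
        logL=st.floats(-1e6, 0),
        p1=st.integers(0, 50),
        extra=st.integers(1, 50),
        n=st.integers(8, 100000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_penalty_monotone_and_aic_vs_bic(self, logL, p1, extra, n):
        assert m.bic(logL, p1 + extra, n) < m.bic(logL, p1, n)
        if np.log(n) > 2:
            assert m.aic(logL, p1) >= m.bic(logL, p1, n)


class TestEntropy:
    def test_one_hot_is_perfectly_separated(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        assert m.entropy(post) == 1.0

    def test_uniform_is_no_separation(self):
        assert m.entropy(np.full((10, 4), 0.25)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        post = np.array([[0.9, 0.1], [0.5, 0.5]])
        # 1 - (0.3251 + 0.6931) / (2 ln 2)
        assert m.entropy(post) == pytest.approx(0.2655, abs=1e-4)

    def test_single_group_defined_as_one(self):
        assert m.entropy(np.ones((5, 1))) == 1.0

    @given(
        raw=arrays(
            float,
            st.tuples(st.integers(2, 20), st.integers(2, 5)),
            elements=st.floats(0.01, 10.0),
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bounds_on_fuzzed_posteriors(self, raw):
        post = raw / raw.sum(axis=1, keepdims=True)
        assert 0.0 <= m.entropy(post) <= 1.0


class TestAppaOccMismatch:
    def test_one_hot_appa_is_one(self):
        post = np.eye(2)[np.array([0, 1, 0])]
        labels = np.array([1, 2, 1])
        assert np.allclose(m.appa(post, labels), 1.0)

    def test_appa_is_group_mean(self):
        post = np.array([[0.9, 0.1], [0.7, 0.3], [0.2, 0.8]])
        labels = np.array([1, 1, 2])
        np.testing.assert_allclose(m.appa(post, labels), [0.8, 0.8])

    def test_appa_matches_brute_force_on_fuzzed_posteriors(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            post = rng.dirichlet(np.ones(3), size=30)
            labels = post.argmax(axis=1) + 1
            expected = [
                np.mean([post[i, j] for i in range(30) if labels[i] == j + 1])
                for j in range(3)
                if (labels == j + 1).any()
            ]
            got = m.appa(post, labels)
            np.testing.assert_allclose(got[~np.isnan(got)], expected)

    @pytest.mark.parametrize(
        "appa_j, pi_j, expected",
        [(0.5, 0.5, 1.0), (0.9, 0.1, 81.0)],
    )
    def test_occ_closed_form(self, appa_j, pi_j, expected):
        assert m.occ(appa_j, pi_j) == pytest.approx(expected)

    def test_occ_against_published_row(self):
        # largest group of the chosen model: share 63.199%, APPA 0.9845982
        assert m.occ(0.9845982, 0.63199) == pytest.approx(37.22547, rel=1e-4)

    def test_occ_cap_at_perfect_assignment(self):
        assert m.occ(1.0, 0.1) == OCC_CAP

    @pytest.mark.parametrize(
        "appa_j, occ_j, expected, digits",
        [
            (0.9845982, 37.22547, 63.2, 1),
            (0.9999979, 95000000.0, 0.50, 2),
            (0.5, 1.0, 50.0, 6),
        ],
    )
    def test_invert_occ(self, appa_j, occ_j, expected, digits):
        assert round(100 * m.invert_occ(appa_j, occ_j), digits) == pytest.approx(expected)

    def test_invert_occ_is_inverse_of_occ(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.uniform(0.5, 0.999)
            p = rng.uniform(0.01, 0.99)
            assert m.invert_occ(a, m.occ(a, p)) == pytest.approx(p, abs=1e-9)

    def test_mismatch_zero_for_exact_assignment(self):
        labels = np.array([1, 1, 2, 2])
        np.testing.assert_allclose(m.mismatch(labels, np.array([0.5, 0.5])), 0.0)

    def test_mismatch_constructed_value_and_zero_sum(self):
        labels = np.array([1, 1, 2, 2])
        out = m.mismatch(labels, np.array([0.49, 0.51]))
        assert out[0] == pytest.approx(0.01)
        rng = np.random.default_rng(12)
        for _ in range(20):
            pi = rng.dirichlet(np.ones(4))
            labels = rng.integers(1, 5, size=100)
            assert m.mismatch(labels, pi).sum() == pytest.approx(0.0, abs=1e-12)


class TestDiagnosticsSelfConsistency:
    def test_occ_recomputed_from_own_posteriors(self, fitted_three):
        d = m.diagnose(fitted_three)
        for j in range(3):
            if d.occ_capped[j]:
                assert d.occ[j] == OCC_CAP
            else:
                assert d.occ[j] == m.occ(d.appa[j], fitted_three.pi[j])

    def test_mismatch_sums_to_zero(self, fitted_three):
        assert m.diagnose(fitted_three).mismatch.sum() == pytest.approx(0.0, abs=1e-12)

    def test_published_diagnostics_invert_to_published_shares(self):
        shares = sorted(
            round(100 * m.invert_occ(a, o), 1) for a, o in SIX_GROUP_DIAGNOSTICS
        )
        assert shares == sorted([63.2, 21.3, 10.7, 2.4, 1.9, 0.5])


class TestEnumeration:
    def test_prefers_true_group_count(self, three_group_sim):
        table = m.enumerate_models(
            three_group_sim.panel,
            range(1, 5),
            m.ModelSpec(n_groups=1, orders=3, seed=0, n_starts=2),
        )
        assert table.best_by("bic_obs") == 3
        assert not table.errors

    def test_single_group_row(self, three_group_sim):
        table = m.enumerate_models(
            three_group_sim.panel, [1], m.ModelSpec(n_groups=1, orders=2, seed=0, n_starts=1)
        )
        row = table.rows[0]
        assert row.n_groups == 1
        assert row.entropy == 1.0
        assert row.smallest_group_pct == 100.0

    def test_reproducible_under_fixed_seed(self, three_group_sim):
        spec = m.ModelSpec(n_groups=1, orders=2, seed=5, n_starts=2)
        a = m.enumerate_models(three_group_sim.panel, [2, 3], spec).to_frame()
        b = m.enumerate_models(three_group_sim.panel, [2, 3], spec).to_frame()
        assert a.equals(b)


class TestAdjustPolynomialOrders:
    def make_constant_panel(self, seed, n=200):
        spec = m.SimulationSpec(
            n_areas=n,
            group_props=np.array([0.5, 0.5]),
            traj_coeffs=np.stack(
                [np.column_stack([np.full(6, 20.0), np.zeros(6)]),
                 np.column_stack([np.full(6, 60.0), np.zeros(6)])]
            ),
            noise_sd=np.full(6, 2.0),
            seed=seed,
        )
        return m.generate_panel(spec).panel

    def test_constant_data_mostly_reduces_to_order_zero(self):
        # Under flat truth the top-term Wald p-values are uniform, so each
        # of the 12 (group, indicator) elimination chains reaches order 0
        # with probability ~0.95^3; across 20 seeds x 12 chains roughly 86%
        # of chains should fully reduce and final orders should be near 0.
        reduced = total = 0
        final_orders = []
        for seed in range(20):
            panel = self.make_constant_panel(seed)
            model = m.fit(panel, m.ModelSpec(n_groups=2, orders=3, seed=seed, n_starts=1))
            adjusted = m.adjust_polynomial_orders(panel, model, alpha=0.05)
            reduced += int((adjusted.orders == 0).sum())
            total += adjusted.orders.size
            final_orders.append(adjusted.orders.mean())
            assert adjusted.n_params <= model.n_params
        assert reduced / total >= 0.75
        assert np.mean(final_orders) < 0.5

    def test_lenient_alpha_keeps_all_terms(self):
        panel = self.make_constant_panel(1)
        model = m.fit(panel, m.ModelSpec(n_groups=2, orders=3, seed=1, n_starts=1))
        adjusted = m.adjust_polynomial_orders(panel, model, alpha=1 - 1e-12)
        np.testing.assert_array_equal(adjusted.orders, model.orders)
        assert adjusted.n_params == model.n_params

    def test_removing_terms_reduces_parameter_count(self):
        panel = self.make_constant_panel(2)
        model = m.fit(panel, m.ModelSpec(n_groups=2, orders=3, seed=2, n_starts=1))
        adjusted = m.adjust_polynomial_orders(panel, model, alpha=0.05)
        if (adjusted.orders < model.orders).any():
            assert adjusted.n_params < model.n_params
        assert "pre_bic_obs" in adjusted.adjustment_report

    def test_alpha_out_of_range_rejected(self, fitted_three, three_group_sim):
        with pytest.raises(ValueError):
            m.adjust_polynomial_orders(three_group_sim.panel, fitted_three, alpha=1.5)
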