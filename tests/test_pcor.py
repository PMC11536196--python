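"""Base correlations, partial correlations and the significance gate."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from symptomnet.criteria import CriterionDefinition
from symptomnet.errors import (
    DegenerateColumnError,
    InsufficientSampleError,
    ParameterError,
)
from symptomnet.pcor import (
    PartialCorrResult,
    _tetrachoric_pair,
    base_correlation,
    build_network,
    partial_correlations,
    phi_matrix,
)

from conftest import random_pd_correlation


def data_from_table(table):
    """Expand a 2x2 count table [[n11,n10],[n01,n00]] into two 0/1 columns."""
    rows = []
    for (a, b), cnt in zip(((1, 1), (1, 0), (0, 1), (0, 0)), table.ravel()):
        rows += [(a, b)] * int(cnt)
    return np.array(rows)


def residual_partial(corr, i, j):
    """Oracle: partial correlation via least-squares residuals."""
    p = corr.shape[0]
    rest = [k for k in range(p) if k not in (i, j)]
    if not rest:
        return corr[i, j]
    s_rr = corr[np.ix_(rest, rest)]
    s_ir = corr[np.ix_([i, j], rest)]
    cond = corr[np.ix_([i, j], [i, j])] - s_ir @ np.linalg.solve(s_rr, s_ir.T)
    return cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])


class TestBaseCorrelation:
    def test_phi_closed_form(self):
        # (ad - bc) / sqrt(margins): (1600-100)/2500 = 0.6
        x = data_from_table(np.array([[40, 10], [10, 40]]))
        assert phi_matrix(x)[0, 1] == pytest.approx(0.6)

    def test_perfect_agreement_phi_one(self):
        x = data_from_table(np.array([[50, 0], [0, 50]]))
        assert phi_matrix(x)[0, 1] == pytest.approx(1.0)

    def test_tetrachoric_against_numeric_integration(self):
        table = np.array([[40, 10], [10, 40]])
        rho_hat, corrected, _ = _tetrachoric_pair(table)
        assert not corrected
        tx = stats.norm.ppf(1 - 0.5)
        ty = stats.norm.ppf(1 - 0.5)

        def p11(rho):
            pdf = lambda y, x: np.exp(
                -(x * x - 2 * rho * x * y + y * y) / (2 * (1 - rho**2))
            ) / (2 * np.pi * np.sqrt(1 - rho**2))
            val, _ = integrate.dblquad(pdf, tx, 8, ty, 8, epsabs=1e-10)
            return val

        from scipy.optimize import brentq
        rho_oracle = brentq(lambda r: p11(r) - 0.4, -0.99, 0.99, xtol=1e-8)
        assert rho_hat == pytest.approx(rho_oracle, abs=1e-4)

    def test_tetrachoric_consistency_for_latent_normal(self):
        rng = np.random.default_rng(0)
        rho = 0.5
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=20_000)
        x = (z > np.array([0.2, -0.4])).astype(int)
        base = base_correlation(x, "tetrachoric")
        assert base.corr[0, 1] == pytest.approx(rho, abs=0.03)
        assert base.effective_n < 20_000  # tetrachoric is noisier than Pearson

    def test_zero_cell_flagged(self):
        x = data_from_table(np.array([[30, 10], [0, 30]]))
        # jitter a third column so no column is constant
        rng = np.random.default_rng(1)
        x = np.column_stack([x, rng.integers(0, 2, x.shape[0])])
        base = base_correlation(x, "tetrachoric")
        assert (0, 1) in base.flagged_pairs

    def test_constant_column_named(self):
        mat = np.column_stack([np.ones(10, dtype=int), np.tile([0, 1], 5)])
        ds_like = mat
        with pytest.raises(DegenerateColumnError):
            base_correlation(ds_like, "phi")


class TestPartialCorrelations:
    def test_identity_gives_zero_partials_unit_pvalues(self):
        res = partial_correlations(np.eye(5), n=100)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(res.pcor[off], 0.0)
        assert np.allclose(res.pvals[off], 1.0)
        assert res.k == 3

    def test_bivariate_partial_is_marginal(self):
        c = np.array([[1.0, 0.42], [0.42, 1.0]])
        res = partial_correlations(c, n=50)
        assert res.pcor[0, 1] == pytest.approx(0.42, abs=1e-12)

    def test_four_variable_residual_regression_oracle(self):
        corr = random_pd_correlation(np.random.default_rng(5), 4)
        res = partial_correlations(corr, n=200)
        for i, j in itertools.combinations(range(4), 2):
            assert res.pcor[i, j] == pytest.approx(
                residual_partial(corr, i, j), abs=1e-10)

    def test_t_transform_pvalue(self):
        # r = 0.10, n = 100, k = 7 -> t ~ 0.959 on 91 df, p ~ 0.340
        pm = np.eye(9)
        pm[0, 1] = pm[1, 0] = 0.10
        from symptomnet.simulate import partial_to_correlation
        corr = partial_to_correlation(pm)
        res = partial_correlations(corr, n=100)
        assert res.pcor[0, 1] == pytest.approx(0.10, abs=1e-10)
        assert res.pvals[0, 1] == pytest.approx(0.34023, abs=5e-4)

    def test_pvalue_decreasing_in_abs_r(self):
        def pval(r):
            c = np.array([[1.0, r], [r, 1.0]])
            return partial_correlations(c, n=30).pvals[0, 1]

        rs = [0.0, 0.1, 0.3, 0.5, 0.9]
        ps = [pval(r) for r in rs]
        assert ps[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_fisher_agrees_with_t_at_large_n(self):
        corr = random_pd_correlation(np.random.default_rng(8), 5)
        a = partial_correlations(corr, n=4000, test="t")
        b = partial_correlations(corr, n=4000, test="fisher")
        assert np.allclose(a.pvals, b.pvals, atol=2e-3)

    def test_insufficient_sample(self):
        with pytest.raises(InsufficientSampleError):
            partial_correlations(np.eye(9), n=9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=3, max_value=8))
    def test_precision_inversion_matches_residual_oracle(self, seed, p):
        corr = random_pd_correlation(np.random.default_rng(seed), p)
        res = partial_correlations(corr, n=100)
        for i, j in itertools.combinations(range(p), 2):
            assert abs(res.pcor[i, j] - residual_partial(corr, i, j)) < 1e-8


class TestJackknifePartials:
    def simulate_binary(self, n, rho=0.5, seed=0):
        rng = np.random.default_rng(seed)
        cov = np.full((4, 4), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(4), cov, size=n)
        return (z > 0).astype(int)

    def test_point_estimate_matches_plain_tetrachoric_path(self):
        from symptomnet.pcor import jackknife_partial_correlations

        x = self.simulate_binary(600)
        jk = jackknife_partial_correlations(x)
        base = base_correlation(x, "tetrachoric")
        plain = partial_correlations(base.corr, base.effective_n,
                                     method="tetrachoric")
        np.testing.assert_allclose(jk.pcor, plain.pcor, atol=1e-12)
        assert jk.test == "jackknife"

    def test_deterministic(self):
        from symptomnet.pcor import jackknife_partial_correlations

        x = self.simulate_binary(400, seed=3)
        a = jackknife_partial_correlations(x)
        b = jackknife_partial_correlations(x)
        np.testing.assert_array_equal(a.pvals, b.pvals)

    def test_needs_enough_rows_per_block(self):
        from symptomnet.pcor import jackknife_partial_correlations

        with pytest.raises(InsufficientSampleError):
            jackknife_partial_correlations(self.simulate_binary(60))

    def test_strong_dependence_detected_noise_not(self):
        from symptomnet.pcor import jackknife_partial_correlations

        rng = np.random.default_rng(9)
        # two dependent columns, two independent ones
        z = rng.multivariate_normal([0, 0], [[1, .6], [.6, 1]], size=800)
        x = np.column_stack([(z > 0).astype(int),
                             rng.integers(0, 2, (800, 2))])
        jk = jackknife_partial_correlations(x)
        assert jk.pvals[0, 1] < 0.01
        assert jk.pvals[2, 3] > 0.05


def make_result(pvals, pcor=None):
    p = pvals.shape[0]
    if pcor is None:
        pcor = np.full((p, p), 0.2)
        np.fill_diagonal(pcor, 1.0)
    return PartialCorrResult(pcor=pcor, pvals=pvals, n=100, k=p - 2,
                             method="phi")


class TestBuildNetwork:
    criteria9 = [CriterionDefinition(f"A{i+1}") for i in range(9)]

    def test_no_significant_edges_empty_network(self):
        pv = np.full((9, 9), 0.5)
        net = build_network(make_result(pv), 0.05, self.criteria9)
        assert net.n_edges == 0

    def test_all_significant_gives_complete_36(self):
        pv = np.full((9, 9), 1e-4)
        net = build_network(make_result(pv), 0.05, self.criteria9)
        assert net.n_edges == 36

    def test_mixed_fixture_matches_threshold_scan(self):
        rng = np.random.default_rng(4)
        pv = np.zeros((9, 9))
        iu = np.triu_indices(9, 1)
        pv[iu] = rng.uniform(0, 0.2, size=36)
        pv = pv + pv.T
        res = make_result(pv)
        net = build_network(res, 0.05, self.criteria9)
        expected = {(i, j) for i, j in zip(*iu) if pv[i, j] < 0.05}
        assert net.edge_set() == expected

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        pv = np.zeros((9, 9))
        iu = np.triu_indices(9, 1)
        pv[iu] = rng.uniform(0, 0.3, size=36)
        pv = pv + pv.T
        res = make_result(pv)
        e1 = build_network(res, 0.01, self.criteria9).edge_set()
        e2 = build_network(res, 0.10, self.criteria9).edge_set()
        assert e1 <= e2

    def test_mtc_is_more_conservative(self):
        rng = np.random.default_rng(2)
        pv = np.zeros((9, 9))
        iu = np.triu_indices(9, 1)
        pv[iu] = rng.uniform(0, 0.1, size=36)
        pv = pv + pv.T
        res = make_result(pv)
        plain = build_network(res, 0.05, self.criteria9).edge_set()
        bonf = build_network(res, 0.05, self.criteria9, mtc="bonferroni").edge_set()
        bh = build_network(res, 0.05, self.criteria9, mtc="bh").edge_set()
        assert bonf <= bh <= plain

    def test_alpha_out_of_range(self):
        with pytest.raises(ParameterError):
            build_network(make_result(np.full((9, 9), 0.5)), 1.5, self.criteria9)

    def test_weights_invariant_to_row_permutation(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 2, size=(300, 9))
        perm = rng.permutation(300)
        r1 = partial_correlations(phi_matrix(x), 300)
        r2 = partial_correlations(phi_matrix(x[perm]), 300)
        n1 = build_network(r1, 0.2, self.criteria9)
        n2 = build_network(r2, 0.2, self.criteria9)
        np.testing.assert_allclose(n1.weight_matrix(), n2.weight_matrix())
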