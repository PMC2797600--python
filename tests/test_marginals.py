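import itertools
import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import invgamma, multivariate_normal, norm

from bpeqtl.data import Hyperparameters, PartitionState, initial_state
from bpeqtl.marginals import (
    DirichletSpec,
    GaussianPriorSpec,
    dense_expression_covariance,
    expression_block_loglik,
    expression_block_tempered,
    log_posterior,
    marker_block_loglik,
    null_gene_loglik,
    null_marker_loglik,
    partition_log_prior,
    tempered_log_posterior,
    type_allocation_log_marginal,
)


class TestDirichletMultinomial:
    def test_uniform_predictive_single_observation(self):
        for C in (2, 3, 5):
            counts = np.zeros((1, C), dtype=int)
            counts[0, 0] = 1
            assert marker_block_loglik(counts, DirichletSpec(1.0)) == pytest.approx(
                math.log(1.0 / C)
            )

    def test_two_one_counts_beta_integral(self):
        # int p^2 (1-p) dp over Beta(1,1) = 1/12
        assert marker_block_loglik(np.array([[2, 1]]), DirichletSpec(1.0)) == pytest.approx(
            math.log(1.0 / 12.0)
        )

    def test_empty_counts_are_free(self):
        assert marker_block_loglik(np.zeros((2, 3), dtype=int), DirichletSpec(0.7)) == 0.0

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError, match="C = 0"):
            marker_block_loglik(np.zeros((1, 0)), DirichletSpec(1.0))

    @pytest.mark.parametrize("n,C", [(2, 2), (3, 3), (4, 2), (3, 4)])
    def test_normalizes_over_ordered_sequences(self, n, C):
        spec = DirichletSpec(0.8)
        total = 0.0
        for seq in itertools.product(range(C), repeat=n):
            counts = np.bincount(seq, minlength=C)[None, :]
            total += math.exp(marker_block_loglik(counts, spec))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_null_marker_cubic_integral(self):
        # int p^3 dp over Beta(1,1) = 1/4
        assert null_marker_loglik(np.array([3, 0]), DirichletSpec(1.0)) == pytest.approx(
            math.log(0.25)
        )

    def test_type_allocation_prefers_fewer_types_on_balanced_data(self):
        one = type_allocation_log_marginal(np.array([10]), 1.0)
        two = type_allocation_log_marginal(np.array([5, 5]), 1.0)
        assert one > two


class TestNullGene:
    def test_quadrature_oracle(self, rng):
        # the mean is integrated by the exact Gaussian convolution
        # (scipy multivariate normal); the variance by 1-D quadrature on
        # the log scale
        for _ in range(5):
            gp = GaussianPriorSpec(*rng.uniform(0.5, 2.0, size=3))
            y = rng.normal(size=3)
            n = len(y)

            def integrand(u):
                s2 = math.exp(u)
                cov = s2 * np.eye(n) + (s2 / gp.kappa) * np.ones((n, n))
                lik = multivariate_normal.pdf(y, np.zeros(n), cov)
                return lik * invgamma.pdf(s2, gp.a0, scale=gp.b0) * s2

            val, _ = integrate.quad(integrand, -15, 12, epsabs=1e-13,
                                    epsrel=1e-11, limit=400)
            assert null_gene_loglik(y, gp) == pytest.approx(math.log(val), abs=1e-7)

    def test_sign_symmetry(self, rng):
        gp = GaussianPriorSpec()
        y = rng.normal(size=7)
        assert null_gene_loglik(y, gp) == pytest.approx(null_gene_loglik(-y, gp))

    def test_independent_genes_additive(self, rng):
        gp = GaussianPriorSpec()
        y1, y2 = rng.normal(size=5), rng.normal(size=5)
        joint = null_gene_loglik(y1, gp) + null_gene_loglik(y2, gp)
        assert joint == pytest.approx(null_gene_loglik(y1, gp) + null_gene_loglik(y2, gp))


def _random_block_case(rng, max_cells=36):
    while True:
        G = int(rng.integers(1, 5))
        N = int(rng.integers(2, 8))
        if G * N <= max_cells:
            break
    K = int(rng.integers(1, min(3, N) + 1))
    types = np.concatenate([np.arange(1, K + 1), rng.integers(1, K + 1, size=N - K)])
    rng.shuffle(types)
    Y = rng.normal(size=(G, N))
    offsets = rng.normal(scale=0.3, size=N)
    s2, s2g, s2t = rng.uniform(0.3, 2.0, size=3)
    return Y, types, offsets, s2, s2g, s2t


class TestExpressionBlock:
    def test_matches_dense_mvn_oracle(self, rng):
        for _ in range(25):
            Y, types, offsets, s2, s2g, s2t = _random_block_case(rng)
            ll = expression_block_loglik(Y, types, offsets, s2, s2g, s2t)
            cov = dense_expression_covariance(Y.shape[0], types, s2, s2g, s2t)
            oracle = multivariate_normal.logpdf(
                (Y - offsets[None, :]).ravel(), np.zeros(cov.shape[0]), cov
            )
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_type_label_permutation_invariant(self, rng):
        Y = rng.normal(size=(2, 6))
        types = np.array([1, 2, 1, 2, 2, 1])
        swapped = np.where(types == 1, 2, 1)
        a = expression_block_loglik(Y, types, np.zeros(6), 1.0, 1.0, 1.0)
        b = expression_block_loglik(Y, swapped, np.zeros(6), 1.0, 1.0, 1.0)
        assert a == pytest.approx(b)

    def test_gene_effect_collapse_limit(self, rng):
        # sigma_gene -> 0 with one gene reduces to N(0, s2 I + s2t J)
        y = rng.normal(size=(1, 5))
        types = np.ones(5, dtype=int)
        ll = expression_block_loglik(y, types, np.zeros(5), 1.0, 1e-12, 0.8)
        cov = np.eye(5) + 0.8 * np.ones((5, 5))
        oracle = multivariate_normal.logpdf(y.ravel(), np.zeros(5), cov)
        assert ll == pytest.approx(oracle, abs=1e-5)

    def test_nonpositive_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            expression_block_loglik(rng.normal(size=(1, 3)), np.ones(3, dtype=int),
                                    np.zeros(3), -1.0, 1.0, 1.0)


class TestTemperedBlock:
    def test_beta_one_equals_marginal(self, rng):
        for _ in range(5):
            Y, types, offsets, s2, s2g, s2t = _random_block_case(rng)
            a = expression_block_loglik(Y, types, offsets, s2, s2g, s2t)
            b = expression_block_tempered(Y, types, offsets, s2, s2g, s2t, 1.0)
            assert a == pytest.approx(b, abs=1e-9)

    def test_quadrature_oracle_at_fractional_beta(self, rng):
        # G=1, K=1, N=2: log int [N(y; a+u, s2 I) N(a; 0, s2g) N(u; 0, s2t)]^b da du
        y = rng.normal(size=(1, 2))
        s2, s2g, s2t, beta = 0.7, 1.3, 0.9, 0.6

        def integrand(a, u):
            lik = np.prod(norm.pdf(y.ravel(), a + u, math.sqrt(s2)))
            dens = lik * norm.pdf(a, 0, math.sqrt(s2g)) * norm.pdf(u, 0, math.sqrt(s2t))
            return dens**beta

        val, _ = integrate.dblquad(integrand, -12, 12, -12, 12)
        got = expression_block_tempered(y, np.ones(2, dtype=int), np.zeros(2),
                                        s2, s2g, s2t, beta)
        assert got == pytest.approx(math.log(val), abs=1e-6)


class TestPartitionPrior:
    def _state(self, gene_ind, marker_ind, types, K, N):
        D = len(K)
        return PartitionState(np.array(gene_ind), np.array(marker_ind),
                              np.array(types), np.array(K),
                              np.ones((D, 4)), np.zeros((D, N)))

    def test_everything_null_costs_nothing(self):
        hp = Hyperparameters(D=1, lambda_K=1.0, lambda_M=1.0)
        st = self._state([0, 0], [0], [[1, 1, 1]], [1], 3)
        assert partition_log_prior(st, hp, np.array([2])) == 0.0

    def test_marker_addition_penalty(self):
        hp = Hyperparameters(D=1, lambda_K=1.0, lambda_M=1.0, lambda_G=0.0)
        base = self._state([0], [0], [[1, 2, 1]], [2], 3)
        added = self._state([0], [1], [[1, 2, 1]], [2], 3)
        T = np.array([2])
        delta = partition_log_prior(added, hp, T) - partition_log_prior(base, hp, T)
        assert delta == pytest.approx(-2.0 * math.log(2.0))

    def test_type_count_penalty(self):
        hp = Hyperparameters(D=1, lambda_K=1.0, lambda_M=1.0, lambda_G=0.0)
        two = self._state([0], [0], [[1, 2, 1]], [2], 3)
        three = self._state([0], [0], [[1, 2, 3]], [3], 3)
        T = np.array([2])
        assert partition_log_prior(three, hp, T) - partition_log_prior(two, hp, T) == pytest.approx(-1.0)

    def test_monotone_in_complexity(self, rng):
        hp = Hyperparameters(D=1)
        T = np.array([2, 2, 2])
        prev = None
        for n_markers in range(3):
            marker_ind = [1] * n_markers + [0] * (3 - n_markers)
            st = self._state([0], marker_ind, [[1, 2, 1, 2]], [2], 4)
            val = partition_log_prior(st, hp, T)
            if prev is not None:
                assert val <= prev
            prev = val


class TestLogPosterior:
    def test_gene_move_locality(self, tiny_dataset, default_hp):
        expr, geno, _ = tiny_dataset
        rng = np.random.default_rng(0)
        st = initial_state(3, 8, 2, default_hp, rng, frac_assigned=0.5)
        st.gene_indicator[:] = 0
        base = log_posterior(st, expr, geno, default_hp)
        moved = st.copy()
        moved.gene_indicator[0] = 1
        delta = log_posterior(moved, expr, geno, default_hp) - base
        # manual: remove null term, add expression-block delta and lambda_G
        from bpeqtl.marginals import GaussianPriorSpec as GP

        gp = GP(default_hp.prior_mean_scale, default_hp.prior_var_shape,
                default_hp.prior_var_scale)
        s2, s2g, s2t, _ = st.variance_params[0]
        block = expression_block_loglik(
            expr.values[[0]], st.type_indicator[0], st.individual_effects[0],
            s2, s2g, s2t)
        expected = block - null_gene_loglik(expr.values[0], gp) - default_hp.lambda_G
        assert delta == pytest.approx(expected, abs=1e-9)

    def test_module_index_permutation_invariant(self, tiny_dataset, default_hp):
        expr, geno, _ = tiny_dataset
        rng = np.random.default_rng(1)
        st = initial_state(3, 8, 2, default_hp, rng, frac_assigned=0.8)
        swapped = st.copy()
        swapped.gene_indicator = np.where(st.gene_indicator == 1, 2,
                                          np.where(st.gene_indicator == 2, 1,
                                                   st.gene_indicator))
        swapped.marker_indicator = np.where(st.marker_indicator == 1, 2,
                                            np.where(st.marker_indicator == 2, 1,
                                                     st.marker_indicator))
        swapped.type_indicator = st.type_indicator[::-1].copy()
        swapped.K = st.K[::-1].copy()
        swapped.variance_params = st.variance_params[::-1].copy()
        swapped.individual_effects = st.individual_effects[::-1].copy()
        a = log_posterior(st, expr, geno, default_hp)
        b = log_posterior(swapped, expr, geno, default_hp)
        assert a == pytest.approx(b)

    def test_tempered_reduces_to_exact_at_beta_one(self, tiny_dataset, default_hp):
        expr, geno, _ = tiny_dataset
        rng = np.random.default_rng(2)
        st = initial_state(3, 8, 2, default_hp, rng, frac_assigned=0.5)
        st.variance_params[:] = rng.uniform(0.5, 1.5, size=st.variance_params.shape)
        a = log_posterior(st, expr, geno, default_hp)
        b = tempered_log_posterior(st, expr, geno, default_hp, 1.0)
        assert a == pytest.approx(b, abs=1e-9)
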