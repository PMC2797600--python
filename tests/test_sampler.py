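import itertools
import math

import numpy as np
import pytest

from bpeqtl.data import Hyperparameters, PartitionState, initial_state
from bpeqtl.marginals import tempered_log_posterior
from bpeqtl.sampler import (
    ExclusionSet,
    SamplerConfig,
    _Chain,
    _prepare_data,
    autocorrelation,
    build_ld_exclusion,
    gene_full_conditional,
    gibbs_update_gene,
    gibbs_update_individual,
    individual_full_conditional,
    marker_transition_probs,
    run_mcmc,
    split_merge_types,
    tempering_swap,
    update_continuous,
)
from bpeqtl.simulate import simulate_dataset, simulate_genotypes


class TestExclusion:
    def test_duplicated_marker_pair_detected(self, rng):
        base = simulate_genotypes(40, 3, rng)
        codes = np.vstack([base.codes, base.codes[0]])
        from bpeqtl.data import GenotypeMatrix

        geno = GenotypeMatrix(codes, ["a", "b", "c", "dup"], 2)
        excl = build_ld_exclusion(geno, 0.9)
        assert (0, 3) in excl

    def test_independent_pair_not_excluded(self, rng):
        geno = simulate_genotypes(120, 2, rng)
        excl = build_ld_exclusion(geno, 0.99)
        assert (0, 1) not in excl

    def test_threshold_one_gives_empty_set(self, rng):
        geno = simulate_genotypes(50, 5, rng)
        assert len(build_ld_exclusion(geno, 1.0)) == 0

    def test_monomorphic_markers_join_no_pair(self):
        from bpeqtl.data import GenotypeMatrix

        codes = np.zeros((2, 10), dtype=np.int64)
        geno = GenotypeMatrix(codes, ["a", "b"], 2)
        assert len(build_ld_exclusion(geno, 0.5)) == 0


class TestConfig:
    def test_ladder_must_start_at_one(self):
        with pytest.raises(ValueError, match="beta = 1"):
            SamplerConfig(n_chains=2, temperatures=[0.9, 0.8])

    def test_ladder_strictly_decreasing(self):
        with pytest.raises(ValueError, match="decreasing"):
            SamplerConfig(n_chains=2, temperatures=[1.0, 1.0])

    def test_default_geometric_ladder(self):
        cfg = SamplerConfig(n_chains=3)
        assert cfg.temperatures[0] == 1.0
        assert len(cfg.temperatures) == 3


class TestKernelConsistency:
    """The compiled target must agree exactly with the reference
    tempered log posterior."""

    def test_chain_logpost_matches_reference(self, small_dataset, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=3, max_types=4)
        excl = build_ld_exclusion(geno, 0.9)
        data = _prepare_data(expr, geno, hp, excl)
        for _ in range(5):
            st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers,
                               hp, rng, frac_assigned=0.5)
            st.variance_params[:, :3] = rng.uniform(0.4, 1.8, size=(3, 3))
            st.individual_effects[:] = rng.normal(scale=0.1,
                                                  size=st.individual_effects.shape)
            for beta in (1.0, 0.7):
                ch = _Chain(st, data, hp, beta)
                assert ch.log_target(hp, beta) == pytest.approx(
                    tempered_log_posterior(st, expr, geno, hp, beta), abs=1e-8
                )

    def test_incremental_caches_survive_sweeps(self, small_dataset, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=3, max_types=4)
        excl = build_ld_exclusion(geno, 0.9)
        data = _prepare_data(expr, geno, hp, excl)
        st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers, hp, rng)
        ch = _Chain(st, data, hp, 1.0)
        for _ in range(100):
            ch.sweep(rng, data, hp, True)
        drifted = ch.log_target(hp, 1.0)
        ch.rebuild(data, hp)
        assert ch.log_target(hp, 1.0) == pytest.approx(drifted, abs=1e-6)


class TestGibbsKernels:
    def test_gene_conditional_sums_to_one(self, small_dataset, default_hp, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers, hp, rng)
        p = gene_full_conditional(0, st, expr, geno, hp)
        assert p.sum() == pytest.approx(1.0)
        assert len(p) == 3

    def test_matching_gene_prefers_its_module(self, rng):
        from bpeqtl.simulate import ModuleDesign, model_from_decomposition

        designs = [ModuleDesign(model_from_decomposition(0.45, 0.45, 0.1), 6,
                                (0, 1), rho=0.9, name="m")]
        expr, geno, truth = simulate_dataset(designs, rng, N=60, M=4, G=10)
        hp = Hyperparameters(D=1, max_types=4)
        st = initial_state(10, 60, 4, hp, rng, frac_assigned=0.0)
        st.gene_indicator[:6] = 1
        st.gene_indicator[0] = 0
        # types follow the first locus
        st.type_indicator[0] = geno.codes[0] + 1
        st.K[0] = 2
        p = gene_full_conditional(0, st, expr, geno, hp)
        assert p[1] > p[0]

    def test_beta_zero_limit_flattens_marker_kernel(self, rng):
        # the marker terms are pure powers of beta, so the hot-chain limit
        # accepts every proposal: transitions approach the flat proposal
        geno = simulate_genotypes(30, 3, rng)
        expr, _, _ = simulate_dataset([], rng, N=30, M=3, G=4)
        hp = Hyperparameters(D=2, max_types=2)
        excl = ExclusionSet(frozenset())
        st = initial_state(4, 30, 3, hp, rng, frac_assigned=0.0)
        probs = marker_transition_probs(0, st, expr, geno, hp, excl, beta=1e-9)
        assert probs[1] == pytest.approx(0.5, abs=1e-6)
        assert probs[2] == pytest.approx(0.5, abs=1e-6)

    def test_single_type_individual_update_is_noop(self, small_dataset, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=1, max_types=1)
        st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers, hp, rng)
        st.type_indicator[:] = 1
        st.K[:] = 1
        out = gibbs_update_individual(0, 1, st.copy(), expr, geno, hp, 1.0, rng)
        assert np.array_equal(out.type_indicator, st.type_indicator)

    def test_separated_types_recognized(self, rng):
        from bpeqtl.simulate import ModuleDesign, model_from_decomposition

        designs = [ModuleDesign(model_from_decomposition(0.9, 0.05, 0.05), 8,
                                (0, 1), h2=0.95, rho=0.95, name="m")]
        expr, geno, _ = simulate_dataset(designs, rng, N=40, M=2, G=8)
        hp = Hyperparameters(D=1, max_types=3)
        st = initial_state(8, 40, 2, hp, rng, frac_assigned=0.0)
        st.gene_indicator[:] = 1
        st.type_indicator[0] = geno.codes[0] + 1
        st.K[0] = 2
        # the conditional for an individual should strongly favour the type
        # matching its genotype class
        i = 0
        cands, p = individual_full_conditional(1, i, st, expr, geno, hp)
        # staying in the genotype-matched type must dominate switching to
        # the other existing class
        stay = switch = 0.0
        for cand, pr in zip(cands, p):
            lab = cand.type_indicator[0, i]
            same_class = (
                cand.type_indicator[0] == lab
            )[geno.codes[0] == geno.codes[0, i]].mean()
            if same_class > 0.5 and (cand.type_indicator[0] == lab).sum() > 1:
                stay += pr
            elif (cand.type_indicator[0] == lab).sum() > 1:
                switch += pr
        assert stay > switch


class TestMarkerKernelInvariance:
    def test_mh_kernel_preserves_conditional_posterior(self, tiny_dataset):
        """pi K = pi for the single-marker MH kernel, exactly."""
        expr, geno, _ = tiny_dataset
        hp = Hyperparameters(D=2, max_types=2, lambda_M=1.0)
        excl = ExclusionSet(frozenset())
        base = initial_state(3, 8, 2, hp, np.random.default_rng(0),
                             frac_assigned=0.0)
        base.gene_indicator[:] = [1, 1, 0]
        base.type_indicator[0] = geno.codes[0] + 1
        base.K[0] = 2
        m = 0
        states = []
        for dest in range(hp.D + 1):
            st = base.copy()
            st.marker_indicator[m] = dest
            states.append(st)
        logpi = np.array([tempered_log_posterior(s, expr, geno, hp, 1.0)
                          for s in states])
        pi = np.exp(logpi - logpi.max())
        pi /= pi.sum()
        K = np.zeros((3, 3))
        for i, st in enumerate(states):
            probs = marker_transition_probs(m, st, expr, geno, hp, excl, 1.0)
            for dest, pr in probs.items():
                K[i, dest] += pr
        assert np.allclose(K.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(pi @ K, pi, atol=1e-10)

    def test_excluded_partner_blocks_entry(self, rng):
        geno = simulate_genotypes(30, 2, rng)
        expr, _, _ = simulate_dataset([], rng, N=30, M=2, G=4)
        hp = Hyperparameters(D=1, max_types=2)
        excl = ExclusionSet(frozenset({frozenset((0, 1))}))
        st = initial_state(4, 30, 2, hp, rng, frac_assigned=0.0)
        st.marker_indicator[:] = [1, 0]
        probs = marker_transition_probs(1, st, expr, geno, hp, excl, 1.0)
        assert probs[1] == 0.0

    def test_capacity_limit_blocks_entry(self, rng):
        geno = simulate_genotypes(30, 4, rng)
        expr, _, _ = simulate_dataset([], rng, N=30, M=4, G=4)
        hp = Hyperparameters(D=1, max_types=2, max_markers_per_module=3)
        excl = ExclusionSet(frozenset())
        st = initial_state(4, 30, 4, hp, rng, frac_assigned=0.0)
        st.marker_indicator[:] = [1, 1, 1, 0]
        probs = marker_transition_probs(3, st, expr, geno, hp, excl, 1.0)
        assert probs[1] == 0.0


class TestSplitMerge:
    def test_bounds_respected(self, tiny_dataset, rng):
        expr, geno, _ = tiny_dataset
        hp = Hyperparameters(D=1, max_types=2)
        st = initial_state(3, 8, 2, hp, rng, frac_assigned=0.5)
        st.type_indicator[0] = 1
        st.K[0] = 1
        for _ in range(40):
            st = split_merge_types(1, st, expr, geno, hp, 1.0, rng)
            assert 1 <= st.K[0] <= 2
            st.validate()

    def test_kernel_preserves_exact_posterior(self, tiny_dataset):
        """Draws from the exact posterior pushed through one split-merge
        step must keep following it (seeded Monte-Carlo check)."""
        expr, geno, _ = tiny_dataset
        hp = Hyperparameters(D=1, max_types=2, lambda_K=1.0)
        rng = np.random.default_rng(99)
        # enumerate set partitions of 8 individuals into <= 2 parts
        parts = [np.ones(8, dtype=np.int64)]
        for mask in range(1, 2**7):
            t = np.ones(8, dtype=np.int64)
            for i in range(1, 8):
                if (mask >> (i - 1)) & 1:
                    t[i] = 2
            parts.append(t)
        base = initial_state(3, 8, 2, hp, np.random.default_rng(0),
                             frac_assigned=0.0)
        base.gene_indicator[:] = [1, 1, 0]
        base.marker_indicator[:] = [1, 0]
        logpi = []
        for t in parts:
            st = base.copy()
            st.type_indicator[0] = t
            st.K[0] = int(t.max())
            logpi.append(tempered_log_posterior(st, expr, geno, hp, 1.0))
        logpi = np.array(logpi)
        pi = np.exp(logpi - logpi.max())
        pi /= pi.sum()

        def key(t):
            # canonical signature of the unordered partition
            return tuple((t == t[0]).astype(int))

        keys = [key(t) for t in parts]
        n_draws = 3000
        draw_idx = rng.choice(len(parts), size=n_draws, p=pi)
        counts = {}
        for idx in draw_idx:
            st = base.copy()
            st.type_indicator[0] = parts[idx]
            st.K[0] = int(parts[idx].max())
            out = split_merge_types(1, st, expr, geno, hp, 1.0, rng)
            k = key(out.type_indicator[0])
            counts[k] = counts.get(k, 0) + 1
        pi_by_key = {}
        for k, p in zip(keys, pi):
            pi_by_key[k] = pi_by_key.get(k, 0.0) + p
        tv = 0.5 * sum(abs(counts.get(k, 0) / n_draws - p)
                       for k, p in pi_by_key.items())
        assert tv < 0.05


class TestContinuousUpdate:
    def test_zero_gene_module_draws_from_prior(self, small_dataset, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=1, max_types=3)
        st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers, hp,
                           rng, frac_assigned=0.0)
        draws = []
        for _ in range(400):
            update_continuous(1, st, expr, geno, hp, 1.0, rng)
            draws.append(st.variance_params[0, 0])
        # IG(1, 1) prior: median = 1/ln 2
        assert np.median(draws) == pytest.approx(1.0 / math.log(2.0), rel=0.25)

    def test_variances_stay_positive(self, small_dataset, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers, hp,
                           rng, frac_assigned=0.6)
        for _ in range(50):
            update_continuous(1, st, expr, geno, hp, 1.0, rng)
            update_continuous(2, st, expr, geno, hp, 1.0, rng)
        assert np.all(st.variance_params > 0)


class TestTemperingSwap:
    def test_identical_states_always_swap(self, tiny_dataset, rng):
        expr, geno, _ = tiny_dataset
        hp = Hyperparameters(D=1, max_types=2)
        st = initial_state(3, 8, 2, hp, rng, frac_assigned=0.5)
        states = [st.copy(), st.copy()]
        _, accepted = tempering_swap(states, [1.0, 0.9], (0, 1), expr, geno, hp, rng)
        assert accepted

    def test_non_adjacent_pair_rejected(self, tiny_dataset, rng):
        expr, geno, _ = tiny_dataset
        hp = Hyperparameters(D=1, max_types=2)
        st = initial_state(3, 8, 2, hp, rng)
        with pytest.raises(ValueError, match="adjacent"):
            tempering_swap([st, st, st], [1.0, 0.9, 0.8], (0, 2), expr, geno, hp, rng)


class TestRunMcmc:
    def test_seeded_determinism(self, small_dataset):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        cfg = SamplerConfig(n_iterations=120, burn_in=40, thinning=2, n_chains=2,
                            temperatures=[1.0, 0.98], seed=5)
        a = run_mcmc(expr, geno, hp, cfg)
        b = run_mcmc(expr, geno, hp, cfg)
        assert np.array_equal(a.gene_snapshots, b.gene_snapshots)
        assert np.array_equal(a.type_snapshots, b.type_snapshots)
        assert np.allclose(a.log_posterior, b.log_posterior)

    def test_zero_post_burn_in_snapshots(self, small_dataset):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        cfg = SamplerConfig(n_iterations=50, burn_in=50, thinning=2, seed=1)
        tr = run_mcmc(expr, geno, hp, cfg)
        assert tr.n_snapshots == 0
        assert len(tr.log_posterior) == 50

    def test_snapshot_count_formula(self, small_dataset):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        cfg = SamplerConfig(n_iterations=100, burn_in=40, thinning=7, seed=1)
        tr = run_mcmc(expr, geno, hp, cfg)
        assert tr.n_snapshots == (100 - 40) // 7

    def test_exclusion_never_violated(self, rng):
        base = simulate_genotypes(40, 4, rng)
        codes = np.vstack([base.codes, base.codes[0]])  # marker 4 = dup of 0
        from bpeqtl.data import GenotypeMatrix

        geno = GenotypeMatrix(codes, [f"m{i}" for i in range(5)], 2)
        expr, _, _ = simulate_dataset([], rng, N=40, M=5, G=10)
        hp = Hyperparameters(D=2, max_types=3, lambda_M=0.0, lambda_G=0.0)
        cfg = SamplerConfig(n_iterations=400, burn_in=100, thinning=1, seed=2)
        tr = run_mcmc(expr, geno, hp, cfg)
        for s in range(tr.n_snapshots):
            mi = tr.marker_snapshots[s]
            assert not (mi[0] != 0 and mi[0] == mi[4])

    def test_null_marker_occupancy_stays_low(self, rng):
        expr, geno, _ = simulate_dataset([], rng, N=60, M=15, G=20)
        hp = Hyperparameters(D=2)
        cfg = SamplerConfig(n_iterations=1500, burn_in=500, thinning=2, seed=3)
        tr = run_mcmc(expr, geno, hp, cfg)
        occupancy = (tr.marker_snapshots > 0).mean()
        assert occupancy < 0.10

    def test_log_posterior_reaches_plateau(self, small_dataset):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        cfg = SamplerConfig(n_iterations=600, burn_in=300, thinning=2, seed=4)
        tr = run_mcmc(expr, geno, hp, cfg)
        first = tr.log_posterior[:100].mean()
        last = tr.log_posterior[-100:].mean()
        assert last >= first - 3 * tr.log_posterior[-100:].std()
        ac = autocorrelation(tr.log_posterior[300:], max_lag=50)
        assert ac[0] == pytest.approx(1.0)
        assert abs(ac[50]) < abs(ac[1]) + 0.5


class TestGibbsGeneWrapper:
    def test_mutation_in_place(self, small_dataset, rng):
        expr, geno, _ = small_dataset
        hp = Hyperparameters(D=2, max_types=3)
        st = initial_state(expr.n_genes, expr.n_individuals, geno.n_markers, hp, rng)
        out = gibbs_update_gene(0, st, expr, geno, hp, 1.0, rng)
        assert out.gene_indicator[0] in range(3)
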