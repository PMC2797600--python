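import numpy as np
import pytest

from bpeqtl.simulate import (
    PRESET_DECOMPOSITIONS,
    ModuleDesign,
    TwoLocusModel,
    anova_decomposition,
    decompose_variance,
    genotype_factor_r2,
    make_presets,
    model_from_decomposition,
    simulate_dataset,
    simulate_genotypes,
    simulate_module,
)


def brute_force_decomposition(mean_table, freq_table):
    """Independent cell-enumeration two-way ANOVA oracle."""
    mu = np.asarray(mean_table, float)
    f = np.asarray(freq_table, float)
    grand = sum(f[j, k] * mu[j, k] for j in range(2) for k in range(2))
    total = sum(f[j, k] * (mu[j, k] - grand) ** 2 for j in range(2) for k in range(2))
    f1 = [f[0].sum(), f[1].sum()]
    f2 = [f[:, 0].sum(), f[:, 1].sum()]
    m1 = [sum(f[j, k] * mu[j, k] for k in range(2)) / f1[j] for j in range(2)]
    m2 = [sum(f[j, k] * mu[j, k] for j in range(2)) / f2[k] for k in range(2)]
    v1 = sum(f1[j] * (m1[j] - grand) ** 2 for j in range(2))
    v2 = sum(f2[k] * (m2[k] - grand) ** 2 for k in range(2))
    return v1 / total, v2 / total, 1.0 - v1 / total - v2 / total


class TestDecomposition:
    def test_additive_model_has_no_epistasis(self):
        model = TwoLocusModel(np.array([[0.0, 1.0], [1.0, 2.0]]), np.full((2, 2), 0.25))
        assert decompose_variance(model) == pytest.approx((0.5, 0.5, 0.0), abs=1e-12)

    def test_xor_model_is_pure_epistasis(self):
        model = TwoLocusModel(np.array([[1.0, 0.0], [0.0, 1.0]]), np.full((2, 2), 0.25))
        assert decompose_variance(model) == pytest.approx((0.0, 0.0, 1.0), abs=1e-12)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(20):
            mean = rng.normal(size=(2, 2))
            freq = rng.dirichlet(np.ones(4)).reshape(2, 2)
            model = TwoLocusModel(mean, freq)
            got = decompose_variance(model)
            want = brute_force_decomposition(mean, freq)
            assert got == pytest.approx(want, abs=1e-12)

    def test_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            TwoLocusModel(np.ones((2, 2)), np.full((2, 2), 0.25))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero genetic variance"):
            anova_decomposition(np.ones((2, 2)), np.full((2, 2), 0.25))


class TestPresets:
    def test_all_presets_match_target_triples(self):
        presets = make_presets()
        for name, design in presets.items():
            got = decompose_variance(design.model)
            want = PRESET_DECOMPOSITIONS[name]
            assert got == pytest.approx(want, abs=0.02), name

    def test_triples_sum_to_one(self):
        for design in make_presets().values():
            assert sum(decompose_variance(design.model)) == pytest.approx(1.0)

    def test_preset_b_is_mostly_epistatic(self):
        b = make_presets()["B"]
        assert decompose_variance(b.model)[2] == pytest.approx(0.895, abs=0.02)

    def test_preset_e_is_locus1_dominated(self):
        e = make_presets()["E"]
        assert decompose_variance(e.model)[0] == pytest.approx(0.748, abs=0.02)


class TestGenotypes:
    def test_allele_frequency_near_half(self, rng):
        geno = simulate_genotypes(120, 500, rng)
        freq = geno.codes.mean(axis=1)
        se = 0.5 / np.sqrt(120)
        assert np.all(np.abs(freq - 0.5) < 4 * se)

    def test_markov_zero_recombination_is_perfect_linkage(self, rng):
        geno = simulate_genotypes(10, 20, rng, markov_r=0.0)
        assert np.all(geno.codes == geno.codes[0])

    def test_markov_free_recombination_decorrelates(self, rng):
        geno = simulate_genotypes(2000, 2, rng, markov_r=0.5)
        r = np.corrcoef(geno.codes)[0, 1]
        assert abs(r) < 0.1

    def test_positions_sorted(self, rng):
        geno = simulate_genotypes(5, 10, rng)
        pos = [p for _, p in geno.positions]
        assert pos == sorted(pos)


class TestModules:
    def test_rho_one_reproduces_core(self, rng):
        geno = simulate_genotypes(50, 2, rng)
        design = ModuleDesign(model_from_decomposition(0.4, 0.4, 0.2), 3, (0, 1),
                              rho=1.0)
        genes, core = simulate_module(design, geno, rng)
        core_std = (core - core.mean()) / core.std()
        assert np.allclose(genes, core_std[None, :], atol=1e-12)

    def test_core_heritability_calibrated(self, rng):
        design = ModuleDesign(model_from_decomposition(0.33, 0.33, 0.34), 1, (0, 1))
        r2 = []
        for _ in range(100):
            geno = simulate_genotypes(120, 2, rng)
            _, core = simulate_module(design, geno, rng)
            r2.append(genotype_factor_r2(core, geno, (0, 1), adjusted=True))
        se = np.std(r2) / np.sqrt(len(r2))
        assert abs(np.mean(r2) - 0.6) < 4 * se

    def test_gene_core_correlation_calibrated(self, rng):
        design = ModuleDesign(model_from_decomposition(0.33, 0.33, 0.34), 20, (0, 1))
        cors = []
        for _ in range(50):
            geno = simulate_genotypes(120, 2, rng)
            genes, core = simulate_module(design, geno, rng)
            cors.extend(np.corrcoef(genes, core)[-1, :-1])
        se = np.std(cors) / np.sqrt(len(cors))
        assert abs(np.mean(cors) - 0.5) < 4 * se


class TestDatasets:
    def test_simI_has_640_true_pairs(self, rng):
        _, _, truth = simulate_dataset("simI", rng, N=20, M=40, G=400)
        assert truth.n_true_pairs == 640

    def test_simII_gene_layout(self, rng):
        _, _, truth = simulate_dataset("simII", rng, N=20, M=40, G=1000)
        sizes = np.bincount(truth.gene_module)[1:]
        assert sizes.tolist() == [60, 60, 40, 40]
        assert (truth.gene_module > 0).sum() == 200
        assert [len(truth.module_markers[d]) for d in range(1, 5)] == [3, 2, 1, 2]

    def test_empty_design_is_pure_noise(self, rng):
        expr, _, truth = simulate_dataset([], rng, N=10, M=5, G=8)
        assert truth.n_true_pairs == 0
        assert (truth.gene_module == 0).all()
        assert expr.values.shape == (8, 10)

    def test_unknown_design_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown design"):
            simulate_dataset("simIII", rng)

    def test_seeded_determinism(self):
        a = simulate_dataset("simI", np.random.default_rng(5), N=15, M=30, G=350)
        b = simulate_dataset("simI", np.random.default_rng(5), N=15, M=30, G=350)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].codes, b[1].codes)
        assert a[2].pairs == b[2].pairs

    def test_module_gene_variance_explained_near_design_value(self, rng):
        # h2 * rho^2 = 0.15 in expectation for every preset
        design = ModuleDesign(model_from_decomposition(0.33, 0.33, 0.34), 10, (0, 1))
        vals = []
        for _ in range(60):
            geno = simulate_genotypes(120, 2, rng)
            genes, _ = simulate_module(design, geno, rng)
            for g in genes:
                vals.append(genotype_factor_r2(g, geno, (0, 1), adjusted=True))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.15) < 4 * se
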