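import numpy as np
import pytest

from bpeqtl.data import ExpressionMatrix, GenotypeMatrix
from bpeqtl.sampler import SampleTrace
from bpeqtl.simulate import simulate_genotypes
from bpeqtl.summary import (
    ModuleCall,
    consensus_modules,
    extract_modules,
    gene_module_posterior,
    interaction_test,
    pair_posterior,
    smooth_marker_posterior,
)


def make_trace(gene_snaps, marker_snaps, D=2, N=4, K=None):
    gene = np.asarray(gene_snaps, dtype=np.int16)
    marker = np.asarray(marker_snaps, dtype=np.int16)
    S = gene.shape[0]
    types = np.ones((S, D, N), dtype=np.int8)
    Ks = np.ones((S, D), dtype=np.int8) if K is None else np.asarray(K, dtype=np.int8)
    return SampleTrace(gene, marker, types, Ks, np.zeros(S),
                       np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64))


class TestPairPosterior:
    def test_constant_co_membership_is_one(self):
        tr = make_trace([[2, 0], [2, 0], [2, 0]], [[2], [2], [2]])
        pp = pair_posterior(tr)
        assert pp[0, 0] == 1.0
        assert pp[1, 0] == 0.0

    def test_null_gene_row_is_zero(self):
        tr = make_trace([[0, 1]] * 4, [[1]] * 4)
        pp = pair_posterior(tr)
        assert np.all(pp[0] == 0.0)

    def test_hand_counted_fractions(self):
        gene = [[1, 1], [1, 2], [2, 1], [0, 1]]
        marker = [[1, 2], [1, 2], [1, 2], [1, 0]]
        pp = pair_posterior(make_trace(gene, marker))
        # gene0 with marker0 share module 1 in snapshots 0, 1 -> 2/4
        assert pp[0, 0] == pytest.approx(0.5)
        # gene1 with marker0 share module 1 in snapshots 0, 2, 3 -> 3/4
        assert pp[1, 0] == pytest.approx(0.75)
        # gene1 with marker1 (module 2) in snapshot 1 only
        assert pp[1, 1] == pytest.approx(0.25)

    def test_empty_trace_rejected(self):
        tr = make_trace(np.zeros((0, 2)), np.zeros((0, 1)))
        with pytest.raises(ValueError, match="empty"):
            pair_posterior(tr)

    def test_invariant_to_module_relabeling(self, rng):
        gene = rng.integers(0, 3, size=(6, 5))
        marker = rng.integers(0, 3, size=(6, 3))
        base = pair_posterior(make_trace(gene, marker))
        perm = np.array([0, 2, 1])
        swapped = pair_posterior(make_trace(perm[gene], perm[marker]))
        assert np.allclose(base, swapped)


class TestGenePosterior:
    def test_constant_trace_is_certain(self):
        tr = make_trace([[1, 2, 0]] * 5, [[1, 2]] * 5)
        labels, probs = gene_module_posterior(tr)
        assert np.all(probs == 1.0)
        assert labels.tolist() == [1, 2, 0]

    def test_label_switching_repaired_by_alignment(self):
        # identical membership, swapped module indices
        tr = make_trace([[1, 1, 2], [2, 2, 1]], [[1, 2], [2, 1]])
        labels, probs = gene_module_posterior(tr)
        assert np.all(probs == 1.0)

    def test_eighty_twenty_split(self):
        gene = [[1, 0]] * 8 + [[0, 0]] * 2
        marker = [[1]] * 10
        labels, probs = gene_module_posterior(make_trace(gene, marker))
        assert labels[0] == 1 and probs[0] == pytest.approx(0.8)
        assert labels[1] == 0 and probs[1] == pytest.approx(1.0)


class TestSmoothing:
    def test_split_posterior_restored_to_single_peak(self, rng):
        geno = simulate_genotypes(60, 2, rng, markov_r=0.0)  # perfectly linked
        post = np.array([0.4, 0.45])
        peaks, smoothed, mask = smooth_marker_posterior(post, geno, window_r2=0.8)
        assert len(peaks) == 1
        assert smoothed[peaks[0]] == pytest.approx(0.85)
        other = 1 - peaks[0]
        assert mask[other]

    def test_three_marker_window_sum(self, rng):
        geno = simulate_genotypes(60, 3, rng, markov_r=0.0)
        post = np.array([0.3, 0.3, 0.3])
        peaks, smoothed, mask = smooth_marker_posterior(post, geno, window_r2=0.8)
        assert smoothed[1] == pytest.approx(0.9)
        assert len(peaks) == 1

    def test_independent_markers_untouched(self, rng):
        geno = simulate_genotypes(500, 3, rng)  # effectively independent
        post = np.array([0.2, 0.7, 0.1])
        peaks, smoothed, mask = smooth_marker_posterior(post, geno, window_r2=0.8)
        assert np.allclose(smoothed, post)
        assert not mask.any()

    def test_cap_at_one(self, rng):
        geno = simulate_genotypes(60, 3, rng, markov_r=0.0)
        post = np.array([0.5, 0.6, 0.4])
        _, smoothed, _ = smooth_marker_posterior(post, geno, window_r2=0.8)
        assert smoothed.max() == 1.0

    def test_window_mass_bounds(self, rng):
        geno = simulate_genotypes(40, 6, rng, markov_r=0.05)
        post = rng.random(6) * 0.3
        _, smoothed, _ = smooth_marker_posterior(post, geno, window_r2=0.5)
        assert np.all(smoothed <= 1.0 + 1e-12)
        assert np.all(smoothed >= post - 1e-12)


class TestExtractModules:
    def test_clean_trace_recovers_membership(self, rng):
        geno = simulate_genotypes(30, 3, rng)
        tr = make_trace([[1, 1, 0]] * 6, [[1, 0, 0]] * 6, D=2, N=30)
        calls = extract_modules(tr, geno, threshold=0.8)
        assert len(calls) == 1
        assert calls[0].genes == [0, 1]
        assert calls[0].markers == [0]

    def test_monotone_in_threshold(self, rng):
        geno = simulate_genotypes(30, 3, rng)
        gene = [[1, 1, 0]] * 7 + [[1, 0, 0]] * 3
        marker = [[1, 0, 0]] * 10
        tr = make_trace(gene, marker, D=2, N=30)
        low = extract_modules(tr, geno, threshold=0.5)
        high = extract_modules(tr, geno, threshold=0.9)
        low_members = {g for c in low for g in c.genes}
        high_members = {g for c in high for g in c.genes}
        assert high_members <= low_members


class TestInteractionTest:
    def _dataset(self, rng, means, n=112, noise=0.4, n_genes=5):
        geno = simulate_genotypes(n, 2, rng)
        cell = geno.codes[0] * 2 + geno.codes[1]
        base = np.array(means)[cell]
        values = np.vstack([
            base + rng.normal(scale=noise, size=n) for _ in range(n_genes)
        ])
        expr = ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)],
                                [f"i{i}" for i in range(n)])
        return expr, geno

    def test_additive_cells_not_significant(self, rng):
        expr, geno = self._dataset(rng, [0.0, 1.0, 1.0, 2.0])
        p = interaction_test(expr, range(5), geno, 0, 1)
        assert p > 0.01

    def test_xor_cells_highly_significant(self, rng):
        expr, geno = self._dataset(rng, [1.0, 0.0, 0.0, 1.0])
        p = interaction_test(expr, range(5), geno, 0, 1)
        assert p < 1e-6

    def test_marker_relabeling_invariance(self, rng):
        expr, geno = self._dataset(rng, [1.0, 0.0, 0.0, 1.0])
        p1 = interaction_test(expr, range(5), geno, 0, 1)
        flipped = GenotypeMatrix(
            np.vstack([1 - geno.codes[0], geno.codes[1]]), ["m0", "m1"], 2)
        p2 = interaction_test(expr, range(5), flipped, 0, 1)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_empty_cell_error_names_cell(self, rng):
        geno = GenotypeMatrix(np.array([[0, 0, 1, 1], [0, 0, 1, 1]]),
                              ["a", "b"], 2)
        expr = ExpressionMatrix(rng.normal(size=(2, 4)), ["g0", "g1"],
                                list("wxyz"))
        with pytest.raises(ValueError, match=r"empty genotype cell \(0, 1\)"):
            interaction_test(expr, [0, 1], geno, 0, 1)

    def test_empty_gene_set_rejected(self, rng):
        expr, geno = self._dataset(rng, [0.0, 1.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="empty gene set"):
            interaction_test(expr, [], geno, 0, 1)


class TestConsensus:
    def _call(self, genes, module=1):
        return ModuleCall(module, list(genes), [1.0] * len(genes), [0], [1.0], 2.0)

    def test_stable_genes_survive(self):
        runs = [[self._call([0, 1, 2])], [self._call([0, 1, 2, 3])]]
        out = consensus_modules(runs, jaccard=0.5)
        assert out and set(out[0].genes) == {0, 1, 2}

    def test_unstable_gene_dropped(self):
        runs = [[self._call([0, 1])], [self._call([0, 5, 6, 7])]]
        out = consensus_modules(runs, jaccard=0.5)
        assert all(1 not in c.genes for c in out)
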