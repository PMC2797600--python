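"""Synthetic eQTL datasets with two-locus epistasis modules.

The generator emulates an inbred cross of haploid strains: ``N``
individuals carry independent Bernoulli(1/2) binary markers, and each
module is built from a "core gene" whose genetic value is a function of a
small set of loci.  A two-locus model is a 2 x 2 table of genotypic means
``mu_jk`` with cell frequencies ``f_jk``; its genetic variance decomposes
into locus-1, locus-2 and epistatic components by a two-way ANOVA under the
cell frequencies.  The core gene adds Gaussian noise scaled so that the
genotypic means explain a target heritability h^2 (default 0.6), and each
module gene is a noisy copy correlated rho (default 0.5) with the
standardized core, so a module gene's variance explained by the genotype
model is h^2 * rho^2 = 0.15 in expectation.

Named presets A..H span the spectrum from balanced additive-plus-epistatic
(A) to almost pure epistasis with no marginal effects (B, H) to one
dominant locus (E, F, G).  Under uniform haploid cell frequencies the mean
table with a prescribed variance decomposition (L1, L2, Epi) has the exact
orthogonal-contrast form ``mu = sqrt(L1) s1 + sqrt(L2) s2 + sqrt(Epi) s1
s2`` with ``s = +/-1`` allele scores, so each preset reproduces its target
decomposition triple by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, GenotypeMatrix

#: (locus1, locus2, epistasis) genetic-variance shares of the named presets.
PRESET_DECOMPOSITIONS: dict[str, tuple[float, float, float]] = {
    "A": (0.338, 0.339, 0.333),
    "B": (0.052, 0.052, 0.895),
    "C": (0.466, 0.441, 0.088),
    "D": (0.133, 0.128, 0.739),
    "E": (0.748, 0.138, 0.128),
    "F": (0.736, 0.231, 0.043),
    "G": (0.743, 0.050, 0.211),
    "H": (0.131, 0.048, 0.821),
}


@dataclass
class TwoLocusModel:
    """Genotypic means and cell frequencies of one two-locus model."""

    mean_table: np.ndarray  # 2 x 2, mu[j, k]
    freq_table: np.ndarray  # 2 x 2, sums to 1

    def __post_init__(self) -> None:
        self.mean_table = np.asarray(self.mean_table, dtype=np.float64)
        self.freq_table = np.asarray(self.freq_table, dtype=np.float64)
        if self.mean_table.shape != (2, 2) or self.freq_table.shape != (2, 2):
            raise ValueError("two-locus tables must be 2 x 2")
        if not np.isclose(self.freq_table.sum(), 1.0):
            raise ValueError("cell frequencies must sum to 1")
        if np.allclose(self.mean_table, self.mean_table.flat[0]):
            raise ValueError("degenerate model: all genotypic means equal")


@dataclass
class MultiLocusModel:
    """General 2^L-cell genotypic-mean table (uniform cell frequencies)."""

    mean_table: np.ndarray  # shape (2,) * L

    def __post_init__(self) -> None:
        self.mean_table = np.asarray(self.mean_table, dtype=np.float64)

    @property
    def freq_table(self) -> np.ndarray:
        return np.full(self.mean_table.shape, 1.0 / self.mean_table.size)


def anova_decomposition(mean_table: np.ndarray, freq_table: np.ndarray):
    """Per-locus main-effect variance proportions plus the epistatic
    remainder of ``Var(mu)`` under the cell frequencies.

    Returns ``(main_props, epi_prop, total_var)`` where ``main_props`` has
    one entry per locus and everything sums to 1.
    """
    mu = np.asarray(mean_table, dtype=np.float64)
    f = np.asarray(freq_table, dtype=np.float64)
    L = mu.ndim
    grand = float((f * mu).sum())
    total = float((f * (mu - grand) ** 2).sum())
    if total <= 0:
        raise ValueError("zero genetic variance")
    mains = []
    for axis in range(L):
        other = tuple(a for a in range(L) if a != axis)
        f_marg = f.sum(axis=other)
        cond = (f * mu).sum(axis=other) / f_marg
        mains.append(float(np.sum(f_marg * (cond - grand) ** 2)) / total)
    epi = 1.0 - sum(mains)
    return np.array(mains), epi, total


def decompose_variance(model: TwoLocusModel) -> tuple[float, float, float]:
    """Two-way ANOVA shares (locus 1, locus 2, epistasis) of the genetic
    variance; the three proportions sum to 1."""
    mains, epi, _ = anova_decomposition(model.mean_table, model.freq_table)
    return float(mains[0]), float(mains[1]), float(epi)


def model_from_decomposition(l1: float, l2: float, epi: float) -> TwoLocusModel:
    """Uniform-frequency two-locus model with unit genetic variance whose
    ANOVA decomposition is the (normalized) triple ``(l1, l2, epi)``."""
    tot = l1 + l2 + epi
    a, b, c = np.sqrt(l1 / tot), np.sqrt(l2 / tot), np.sqrt(epi / tot)
    s = np.array([1.0, -1.0])
    mean = a * s[:, None] + b * s[None, :] + c * np.outer(s, s)
    return TwoLocusModel(mean, np.full((2, 2), 0.25))


@dataclass
class ModuleDesign:
    """One simulated module: a genotypic-mean model over its loci, the gene
    count, the core-gene heritability and the mean gene-core correlation."""

    model: TwoLocusModel | MultiLocusModel
    n_genes: int
    loci: tuple[int, ...]
    h2: float = 0.6
    rho: float = 0.5
    rho_dispersion: float = 0.0  # sd of per-gene correlations around rho
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if len(self.loci) != self.model.mean_table.ndim:
            raise ValueError("number of loci must match the mean table")


def make_presets(n_genes: int = 40, h2: float = 0.6, rho: float = 0.5) -> dict[str, ModuleDesign]:
    """The eight named two-locus module designs A..H (loci unset: 0, 1)."""
    return {
        name: ModuleDesign(
            model_from_decomposition(*triple), n_genes, (0, 1), h2, rho, name=name
        )
        for name, triple in PRESET_DECOMPOSITIONS.items()
    }


@dataclass
class TruthManifest:
    """Ground truth of one simulated dataset."""

    gene_module: np.ndarray  # length G, 0 = null
    module_markers: dict[int, tuple[int, ...]]  # module -> marker indices
    pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pairs:
            self.pairs = {
                (int(g), int(m))
                for g in np.where(self.gene_module > 0)[0]
                for m in self.module_markers[int(self.gene_module[g])]
            }

    @property
    def n_true_pairs(self) -> int:
        return len(self.pairs)


def simulate_genotypes(
    N: int,
    M: int,
    rng: np.random.Generator,
    markov_r: float | None = None,
) -> GenotypeMatrix:
    """Binary marker matrix for N haploid individuals.

    Default: independent Bernoulli(1/2) per marker.  With ``markov_r``,
    markers form a first-order Markov chain along their order with
    recombination fraction ``markov_r`` between adjacent markers
    (0 = perfect linkage, 0.5 = free recombination).
    """
    if N < 1 or M < 1:
        raise ValueError("N and M must be >= 1")
    if markov_r is None:
        codes = rng.integers(0, 2, size=(M, N))
    else:
        codes = np.empty((M, N), dtype=np.int64)
        codes[0] = rng.integers(0, 2, size=N)
        for m in range(1, M):
            flip = rng.random(N) < markov_r
            codes[m] = np.where(flip, 1 - codes[m - 1], codes[m - 1])
    ids = [f"mrk{m}" for m in range(M)]
    positions = [("chr1", 1000 * (m + 1)) for m in range(M)]
    return GenotypeMatrix(codes.astype(np.int64), ids, 2, positions)


def simulate_module(
    design: ModuleDesign, geno: GenotypeMatrix, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one module's expression block.

    The core gene is ``mu(genotype) + e`` with ``e`` scaled so the
    genotypic means explain ``h2`` of the core variance in expectation.
    Each module gene is ``rho_g * core_std + sqrt(1 - rho_g^2) * noise``,
    standardized.  Returns ``(genes_block, core)`` with shapes
    ``(n_genes, N)`` and ``(N,)``.
    """
    mu = design.model.mean_table
    f = design.model.freq_table
    idx = tuple(geno.codes[m] for m in design.loci)
    genetic = mu[idx]
    _, _, var_g = anova_decomposition(mu, f)
    noise_var = var_g * (1.0 - design.h2) / design.h2
    core = genetic + rng.normal(0.0, np.sqrt(noise_var), size=geno.n_individuals)
    core_std = (core - core.mean()) / core.std()
    genes = np.empty((design.n_genes, geno.n_individuals))
    for j in range(design.n_genes):
        rho_g = design.rho
        if design.rho_dispersion > 0:
            rho_g = float(np.clip(rng.normal(design.rho, design.rho_dispersion), 0.05, 1.0))
        raw = rho_g * core_std + np.sqrt(1.0 - rho_g**2) * rng.normal(
            size=geno.n_individuals
        )
        genes[j] = (raw - raw.mean()) / raw.std()
    return genes, core


def _multi_locus_mix() -> MultiLocusModel:
    # three-locus model: equal additive shares plus a three-way interaction
    s = np.array([1.0, -1.0])
    mean = (
        s[:, None, None] + s[None, :, None] + s[None, None, :]
        + s[:, None, None] * s[None, :, None] * s[None, None, :]
    ) / 2.0
    return MultiLocusModel(mean)


def _single_locus() -> MultiLocusModel:
    return MultiLocusModel(np.array([1.0, -1.0]))


def simulate_dataset(
    design: str | list[ModuleDesign],
    rng: np.random.Generator,
    N: int = 120,
    M: int = 500,
    G: int = 1000,
    markov_r: float | None = None,
) -> tuple[ExpressionMatrix, GenotypeMatrix, TruthManifest]:
    """Simulate a full dataset.

    ``design="simI"``: eight modules (presets A..H) of 40 genes, two loci
    each, remaining genes pure N(0, 1) noise; ``design="simII"``: four
    modules of 60, 60, 40 and 40 genes controlled by 3, 2, 1 and 2 markers.
    A custom list of :class:`ModuleDesign` (with loci set) may be given
    instead; an empty list yields an all-noise dataset.
    """
    geno = simulate_genotypes(N, M, rng, markov_r)
    if isinstance(design, str):
        if design == "simI":
            loci = rng.choice(M, size=16, replace=False)
            presets = make_presets()
            designs = []
            for j, name in enumerate(sorted(presets)):
                dd = presets[name]
                dd.loci = (int(loci[2 * j]), int(loci[2 * j + 1]))
                designs.append(dd)
        elif design == "simII":
            loci = rng.choice(M, size=8, replace=False)
            designs = [
                ModuleDesign(_multi_locus_mix(), 60, tuple(int(x) for x in loci[:3]), name="II-1"),
                ModuleDesign(model_from_decomposition(*PRESET_DECOMPOSITIONS["C"]), 60,
                             (int(loci[3]), int(loci[4])), name="II-2"),
                ModuleDesign(_single_locus(), 40, (int(loci[5]),), name="II-3"),
                ModuleDesign(model_from_decomposition(*PRESET_DECOMPOSITIONS["B"]), 40,
                             (int(loci[6]), int(loci[7])), name="II-4"),
            ]
        else:
            raise ValueError(f"unknown design name: {design!r}")
    else:
        designs = design

    n_module_genes = sum(dd.n_genes for dd in designs)
    if n_module_genes > G:
        raise ValueError("module genes exceed total gene count")
    values = np.empty((G, N))
    gene_module = np.zeros(G, dtype=np.int64)
    module_markers: dict[int, tuple[int, ...]] = {}
    row = 0
    for d, dd in enumerate(designs, start=1):
        block, _ = simulate_module(dd, geno, rng)
        values[row : row + dd.n_genes] = block
        gene_module[row : row + dd.n_genes] = d
        module_markers[d] = tuple(dd.loci)
        row += dd.n_genes
    noise = rng.normal(size=(G - row, N))
    # standardize the noise genes too so all rows are comparable
    if G - row:
        noise = (noise - noise.mean(axis=1, keepdims=True)) / noise.std(axis=1, keepdims=True)
        values[row:] = noise
    expr = ExpressionMatrix(values, [f"gene{g}" for g in range(G)], [f"ind{i}" for i in range(N)])
    truth = TruthManifest(gene_module, module_markers)
    return expr, geno, truth


def genotype_factor_r2(y: np.ndarray, geno: GenotypeMatrix, loci: tuple[int, ...],
                       adjusted: bool = False) -> float:
    """R-squared of a trait regressed on the full genotype-cell factor of
    ``loci`` (one mean per observed genotype combination)."""
    combo = np.zeros(geno.n_individuals, dtype=np.int64)
    for m in loci:
        combo = combo * int(geno.T[m]) + geno.codes[m]
    _, inv = np.unique(combo, return_inverse=True)
    n_cells = inv.max() + 1
    cell_means = np.bincount(inv, weights=y) / np.bincount(inv)
    fitted = cell_means[inv]
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if adjusted:
        n = len(y)
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_cells)
    return r2
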