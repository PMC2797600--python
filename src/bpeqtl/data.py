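"""Domain containers for expression/genotype data and partition states.

The Bayesian partition model jointly clusters expression traits (genes),
genetic markers, and individuals.  A dataset is a pair of aligned matrices:
an :class:`ExpressionMatrix` (genes x individuals, log-ratio values) and a
:class:`GenotypeMatrix` (markers x individuals, small integer codes).  One
MCMC state is a :class:`PartitionState`: gene and marker indicators over
``{0, ..., D}`` (0 = null module) and, for each non-null module, a latent
partition of the individuals into "types" plus the sampled continuous
parameters (variance components and per-individual random effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass
class ExpressionMatrix:
    """Standardized expression traits, genes x individuals.

    ``values[g, i]`` is the (log-ratio) expression of gene ``g`` in
    individual ``i``.
    """

    values: np.ndarray
    gene_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} rows")
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n} columns"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.values.shape[1]


@dataclass
class GenotypeMatrix:
    """Genotype codes, markers x individuals.

    Codes are 0-based integers in ``{0, ..., T-1}``; a haploid biallelic
    cross uses ``T = 2`` (0 = one parental allele, 1 = the other), a diploid
    F2 would use ``T = 3``.  ``T`` may be given per marker or as one scalar.
    """

    codes: np.ndarray
    marker_ids: list[str]
    T: np.ndarray | int = 2
    positions: Optional[list[tuple[str, int]]] = None  # (chrom, coordinate)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("genotype codes must be integers")
        self.codes = self.codes.astype(np.int64)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D matrix")
        m = self.codes.shape[0]
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} rows")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        self.T = np.broadcast_to(np.asarray(self.T, dtype=np.int64), (m,)).copy()
        if np.any(self.T < 2):
            raise ValueError("each marker needs at least 2 genotype codes")
        if self.codes.size and (self.codes.min() < 0 or np.any(self.codes.max(axis=1) >= self.T)):
            bad = np.where(self.codes.max(axis=1) >= self.T)[0]
            raise ValueError(
                f"genotype codes out of range for markers {bad.tolist()[:5]}"
            )
        if self.positions is not None:
            if len(self.positions) != m:
                raise ValueError("positions length mismatch")
            by_chrom: dict[str, int] = {}
            for chrom, pos in self.positions:
                if chrom in by_chrom and pos < by_chrom[chrom]:
                    raise ValueError(f"positions not sorted within {chrom}")
                by_chrom[chrom] = pos

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]


@dataclass
class Hyperparameters:
    """Prior settings of the partition model.

    Parameters
    ----------
    D
        Number of non-null modules (fixed, user belief about the upper
        bound on distinct modules; extraneous modules simply stay empty).
    dirichlet_conc
        Symmetric Dirichlet concentration for the type-specific multinomial
        frequency vectors over the ``T^{M_d}`` genotype combinations.
    type_conc
        Symmetric Dirichlet concentration for the per-module type
        proportions (the mixture weights of the latent individual types);
        collapsed, this gives a Dirichlet-multinomial marginal over the
        type counts that keeps the number of occupied types in check.
    prior_mean_scale, prior_var_shape, prior_var_scale
        Normal-inverse-gamma prior for null-component gene means/variances
        and inverse-gamma(shape, scale) prior for the module variance
        components.
    prior_r_shape, prior_r_scale
        Inverse-gamma prior for the individual-effect variance sigma_r^2.
        The default pins it near 0.01: after quantile normalization and
        per-gene standardization, per-individual offsets are small by
        construction, and a loose prior would let the free individual
        effects absorb the latent-type signal.
    lambda_K, lambda_M, lambda_G
        Complexity-penalty coefficients of the exponential prior on the
        indicators: log prior = -sum_d [lambda_K (K_d - 1)
        + lambda_M K_d M_d log T + lambda_G G_d].
    """

    D: int
    dirichlet_conc: float = 1.0
    type_conc: float = 1.0
    prior_mean_scale: float = 1.0
    prior_var_shape: float = 1.0
    prior_var_scale: float = 1.0
    prior_r_shape: float = 50.0
    prior_r_scale: float = 0.5
    lambda_K: float = 2.0
    lambda_M: float = 5.0
    lambda_G: float = 6.0
    max_markers_per_module: int = 3
    max_types: int = 9

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if min(self.lambda_K, self.lambda_M, self.lambda_G) < 0:
            raise ValueError("penalty coefficients must be >= 0")
        for name in ("dirichlet_conc", "type_conc", "prior_mean_scale", "prior_var_shape", "prior_var_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.max_markers_per_module < 1 or self.max_types < 1:
            raise ValueError("max_markers_per_module and max_types must be >= 1")


@dataclass
class PartitionState:
    """One joint state of the sampler.

    ``gene_indicator[g]`` and ``marker_indicator[m]`` live in
    ``{0, ..., D}`` with 0 the null module.  ``type_indicator[d - 1, i]``
    is the type (``1..K[d-1]``) of individual ``i`` in module ``d``; type
    labels are kept compact (canonical set-partition: labels ordered by
    first occurrence).  ``variance_params[d - 1]`` holds
    ``(sigma2_err, sigma2_gene, sigma2_type, sigma2_indiv)`` and
    ``individual_effects[d - 1]`` the sampled random effects ``r_i``.
    """

    gene_indicator: np.ndarray
    marker_indicator: np.ndarray
    type_indicator: np.ndarray  # D x N, labels 1..K[d]
    K: np.ndarray  # length D
    variance_params: np.ndarray  # D x 4, columns: err, gene, type, indiv
    individual_effects: np.ndarray  # D x N

    def copy(self) -> "PartitionState":
        return PartitionState(
            self.gene_indicator.copy(),
            self.marker_indicator.copy(),
            self.type_indicator.copy(),
            self.K.copy(),
            self.variance_params.copy(),
            self.individual_effects.copy(),
        )

    @property
    def D(self) -> int:
        return self.type_indicator.shape[0]

    def module_genes(self, d: int) -> np.ndarray:
        return np.where(self.gene_indicator == d)[0]

    def module_markers(self, d: int) -> np.ndarray:
        return np.where(self.marker_indicator == d)[0]

    def validate(self) -> None:
        D, N = self.type_indicator.shape
        for d in range(1, D + 1):
            t = self.type_indicator[d - 1]
            k = self.K[d - 1]
            labels = np.unique(t)
            if not np.array_equal(labels, np.arange(1, k + 1)):
                raise ValueError(
                    f"module {d}: type labels {labels.tolist()} not compact 1..{k}"
                )
            if np.any(self.variance_params[d - 1] <= 0):
                raise ValueError(f"module {d}: non-positive variance parameter")

    def canonicalize_types(self, d: int) -> None:
        """Relabel module ``d``'s types by order of first occurrence."""
        t = self.type_indicator[d - 1]
        _, canon = np.unique(t, return_inverse=True)
        # order of first occurrence, not sorted label order
        order = {}
        new = np.empty_like(t)
        nxt = 1
        for i, lab in enumerate(t):
            if lab not in order:
                order[lab] = nxt
                nxt += 1
            new[i] = order[lab]
        self.type_indicator[d - 1] = new
        self.K[d - 1] = nxt - 1


def initial_state(
    n_genes: int,
    n_individuals: int,
    n_markers: int,
    hp: Hyperparameters,
    rng: np.random.Generator,
    frac_assigned: float = 0.1,
) -> PartitionState:
    """Random initialization: a fraction of genes/markers spread uniformly
    over modules, the rest null; every module starts with K = 2 random types.
    """
    D = hp.D
    gene_ind = np.zeros(n_genes, dtype=np.int64)
    sel = rng.random(n_genes) < frac_assigned
    gene_ind[sel] = rng.integers(1, D + 1, size=int(sel.sum()))
    marker_ind = np.zeros(n_markers, dtype=np.int64)
    seln = rng.random(n_markers) < frac_assigned
    # respect max_markers_per_module at init
    cand = np.where(seln)[0]
    rng.shuffle(cand)
    counts = np.zeros(D + 1, dtype=np.int64)
    for m in cand:
        d = int(rng.integers(1, D + 1))
        if counts[d] < hp.max_markers_per_module:
            marker_ind[m] = d
            counts[d] += 1
    types = np.ones((D, n_individuals), dtype=np.int64)
    K = np.ones(D, dtype=np.int64)
    var0 = np.ones((D, 4), dtype=np.float64)
    var0[:, 3] = hp.prior_r_scale / max(hp.prior_r_shape - 1.0, 1.0)  # prior mean
    state = PartitionState(
        gene_ind,
        marker_ind,
        types,
        K,
        var0,
        np.zeros((D, n_individuals), dtype=np.float64),
    )
    for d in range(1, D + 1):
        t = rng.integers(1, 3, size=n_individuals)
        state.type_indicator[d - 1] = t
        state.canonicalize_types(d)
    return state


@dataclass
class ValidationReport:
    n_genes: int
    n_markers: int
    n_individuals: int
    constant_genes: list[str] = field(default_factory=list)
    monomorphic_markers: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def n_issues(self) -> int:
        return len(self.constant_genes) + len(self.monomorphic_markers)

    @property
    def valid(self) -> bool:
        return self.n_issues == 0


def validate_dataset(expr: ExpressionMatrix, geno: GenotypeMatrix) -> ValidationReport:
    """Check that the two matrices describe the same individuals and flag
    degenerate rows (constant genes, monomorphic markers).

    Raises only on an individual-count mismatch; everything else is
    reported.
    """
    if expr.n_individuals != geno.n_individuals:
        raise ValueError(
            f"expression has {expr.n_individuals} individuals but genotypes "
            f"have {geno.n_individuals}"
        )
    report = ValidationReport(expr.n_genes, geno.n_markers, expr.n_individuals)
    if np.isnan(expr.values).any():
        n_missing = int(np.isnan(expr.values).sum())
        report.messages.append(f"{n_missing} missing expression values")
    sd = expr.values.std(axis=1)
    for g in np.where(sd == 0)[0]:
        report.constant_genes.append(expr.gene_ids[g])
    for m in range(geno.n_markers):
        if np.unique(geno.codes[m]).size < 2:
            report.monomorphic_markers.append(geno.marker_ids[m])
    return report


def quantile_normalize_columns(values: np.ndarray) -> np.ndarray:
    """Force every column (individual) onto the common distribution given
    by the mean of the sorted columns; ties share the average rank."""
    g, n = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=np.float64)
    for j in range(n):
        ranks = rankdata(values[:, j], method="average")  # 1..g, halves on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return out


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize individuals to a common distribution, then center
    and scale each gene to mean 0 and standard deviation 1."""
    if np.isnan(raw.values).any():
        raise ValueError("missing values: impute or filter before normalizing")
    qn = quantile_normalize_columns(raw.values)
    mu = qn.mean(axis=1, keepdims=True)
    sd = qn.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = [raw.gene_ids[g] for g in np.where(sd[:, 0] == 0)[0]]
        raise ValueError(f"constant genes after normalization: {bad[:5]}")
    return ExpressionMatrix((qn - mu) / sd, list(raw.gene_ids), list(raw.individual_ids))


@dataclass
class ModuleSufficientStats:
    """Sufficient statistics of one module.

    Expression side: per-(gene, type) sums and counts of ``y``.  Marker
    side: per-type counts over the ``prod(T_m)`` genotype combinations of
    the module's markers.  Additive over disjoint individual sets, and
    incrementally updatable one individual at a time.
    """

    genes: np.ndarray
    markers: np.ndarray
    K: int
    n_combos: int
    expr_sums: np.ndarray  # G_d x K
    expr_counts: np.ndarray  # K (individuals per type)
    combo_counts: np.ndarray  # K x n_combos
    members: list[list[int]]  # individuals per type

    @classmethod
    def empty(cls, genes, markers, K: int, n_combos: int) -> "ModuleSufficientStats":
        genes = np.asarray(genes, dtype=np.int64)
        markers = np.asarray(markers, dtype=np.int64)
        return cls(
            genes,
            markers,
            K,
            n_combos,
            np.zeros((len(genes), K)),
            np.zeros(K, dtype=np.int64),
            np.zeros((K, n_combos), dtype=np.int64),
            [[] for _ in range(K)],
        )

    def _combo_index(self, geno: GenotypeMatrix, i: int) -> int:
        idx = 0
        for m in self.markers:
            idx = idx * int(geno.T[m]) + int(geno.codes[m, i])
        return idx

    def add_individual(self, i: int, k: int, expr: ExpressionMatrix, geno: GenotypeMatrix) -> None:
        self.expr_sums[:, k - 1] += expr.values[self.genes, i]
        self.expr_counts[k - 1] += 1
        if self.n_combos:
            self.combo_counts[k - 1, self._combo_index(geno, i)] += 1
        self.members[k - 1].append(i)

    def remove_individual(self, i: int, k: int, expr: ExpressionMatrix, geno: GenotypeMatrix) -> None:
        self.expr_sums[:, k - 1] -= expr.values[self.genes, i]
        self.expr_counts[k - 1] -= 1
        if self.n_combos:
            self.combo_counts[k - 1, self._combo_index(geno, i)] -= 1
        self.members[k - 1].remove(i)

    def __add__(self, other: "ModuleSufficientStats") -> "ModuleSufficientStats":
        out = ModuleSufficientStats.empty(self.genes, self.markers, self.K, self.n_combos)
        out.expr_sums = self.expr_sums + other.expr_sums
        out.expr_counts = self.expr_counts + other.expr_counts
        out.combo_counts = self.combo_counts + other.combo_counts
        out.members = [a + b for a, b in zip(self.members, other.members)]
        return out


def module_stats(
    state: PartitionState,
    d: int,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    individuals: Optional[Sequence[int]] = None,
) -> ModuleSufficientStats:
    """Sufficient statistics of module ``d`` under ``state``, optionally
    restricted to a subset of individuals."""
    if not 1 <= d <= state.D:
        raise ValueError(f"module index {d} out of range 1..{state.D}")
    genes = state.module_genes(d)
    markers = state.module_markers(d)
    n_combos = int(np.prod(geno.T[markers])) if len(markers) else 0
    stats = ModuleSufficientStats.empty(genes, markers, int(state.K[d - 1]), n_combos)
    if individuals is None:
        individuals = range(expr.n_individuals)
    for i in individuals:
        stats.add_individual(int(i), int(state.type_indicator[d - 1, i]), expr, geno)
    return stats
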