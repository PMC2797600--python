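"""Collapsed log marginal likelihoods and the partition prior.

Module expression block.  Within module ``d`` each trait value is an ANOVA
sum ``y_{g,i} = alpha_g + mu_{k(i)} + r_i + eps_{g,i}`` with gene effects
``alpha_g ~ N(0, sigma_a^2)``, type effects ``mu_k ~ N(0, sigma_t^2)``
shared across the module's genes, sampled individual effects ``r_i`` and
i.i.d. errors ``eps ~ N(0, sigma^2)``.  ``alpha`` and ``mu`` are integrated
analytically: after subtracting the offsets ``r``, the block is a zero-mean
Gaussian with covariance ``sigma^2 I + sigma_a^2 (same-gene blocks)
+ sigma_t^2 (same-type blocks)`` and its log density has a closed form via
the Woodbury identity with a (G_d + K_d)-dimensional capacity matrix,
reduced here to a K_d x K_d solve.

Module marker block.  Conditional on the individual type, the joint
genotype pattern over the module's markers (one of ``C = prod T_m``
combinations) is multinomial with a type-specific frequency vector carrying
a symmetric Dirichlet prior; integrating the frequencies gives a
Dirichlet-multinomial marginal per type (exchangeable-sequence form: no
multinomial coefficient).

Null components.  A null gene is a normal-inverse-gamma collapsed marginal
(multivariate Student-t); a null marker is a single-group
Dirichlet-multinomial.

Partition prior.  An exponential penalty on model complexity:
``log prior = -sum_d [lambda_K (K_d - 1) + lambda_M K_d sum_m log T_m
+ lambda_G G_d]``, strictly decreasing when a type or a marker is added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .data import (
    ExpressionMatrix,
    GenotypeMatrix,
    Hyperparameters,
    PartitionState,
)

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianPriorSpec:
    """Normal-inverse-gamma prior: mean ~ N(0, sigma^2 / kappa),
    sigma^2 ~ InvGamma(a0, b0)."""

    kappa: float = 1.0
    a0: float = 1.0
    b0: float = 1.0

    def __post_init__(self) -> None:
        if min(self.kappa, self.a0, self.b0) <= 0:
            raise ValueError("kappa, a0, b0 must be > 0")


@dataclass
class DirichletSpec:
    """Symmetric Dirichlet concentration over genotype-combination cells."""

    concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


def dirichlet_multinomial_logmarginal(counts: np.ndarray, gamma: float, C: int) -> float:
    """Log marginal of one count vector under a symmetric Dirichlet(gamma)
    prior over C cells, for an exchangeable sequence (ordered observations,
    no multinomial coefficient)."""
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum()
    return float(
        gammaln(C * gamma)
        - gammaln(C * gamma + n)
        + np.sum(gammaln(gamma + counts))
        - C * gammaln(gamma)
    )


def marker_block_loglik(counts_by_type: np.ndarray, dir: DirichletSpec) -> float:
    """Sum over individual types of the Dirichlet-multinomial marginal of
    the type's genotype-combination counts.

    ``counts_by_type`` is K x C with ``C = prod T_m`` over the module's
    markers.
    """
    counts_by_type = np.atleast_2d(np.asarray(counts_by_type))
    C = counts_by_type.shape[1]
    if C == 0:
        raise ValueError("C = 0: marker block needs at least one cell")
    if np.any(counts_by_type < 0):
        raise ValueError("negative counts")
    g = dir.concentration
    return float(
        sum(dirichlet_multinomial_logmarginal(row, g, C) for row in counts_by_type)
    )


def null_marker_loglik(counts: np.ndarray, dir: DirichletSpec) -> float:
    """Single-group Dirichlet-multinomial marginal of one marker's genotype
    counts over its T codes."""
    counts = np.asarray(counts)
    return dirichlet_multinomial_logmarginal(counts, dir.concentration, len(counts))


def null_gene_loglik(y: np.ndarray, gp: GaussianPriorSpec) -> float:
    """Exact normal-inverse-gamma collapsed marginal of one null gene
    (multivariate Student-t form)."""
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 1:
        raise ValueError("need at least one observation")
    s = y.sum()
    bn = gp.b0 + 0.5 * (np.dot(y, y) - s * s / (gp.kappa + n))
    return float(
        -0.5 * n * LOG2PI
        + 0.5 * np.log(gp.kappa / (gp.kappa + n))
        + gp.a0 * np.log(gp.b0)
        - gammaln(gp.a0)
        + gammaln(gp.a0 + 0.5 * n)
        - (gp.a0 + 0.5 * n) * np.log(bn)
    )


def expression_block_suffstats(
    Y_sub: np.ndarray, types: np.ndarray, offsets: np.ndarray
):
    """Scalars/vectors sufficient for the collapsed expression block:
    (G, K, n_k, sum_g u_g, sum_g u_g^2, z^T z, per-type totals v_k)."""
    Y_sub = np.atleast_2d(np.asarray(Y_sub, dtype=np.float64))
    types = np.asarray(types, dtype=np.int64)
    Z = Y_sub - np.asarray(offsets, dtype=np.float64)[None, :]
    K = int(types.max()) if types.size else 0
    n_k = np.bincount(types - 1, minlength=K).astype(np.float64)
    u = Z.sum(axis=1)
    v = np.zeros(K)
    for k in range(K):
        v[k] = Z[:, types == k + 1].sum()
    return Z.shape[0], K, n_k, float(u.sum()), float(np.dot(u, u)), float((Z * Z).sum()), v


def expression_block_loglik_core(
    G: int,
    K: int,
    n_k: np.ndarray,
    u_sum: float,
    u_sq: float,
    zz: float,
    v: np.ndarray,
    sigma2: float,
    sigma2_gene: float,
    sigma2_type: float,
) -> float:
    """Collapsed expression-block log likelihood from sufficient statistics.

    Empty types (n_k = 0) contribute exactly zero and may be included.
    """
    if G == 0:
        return 0.0
    if min(sigma2, sigma2_gene, sigma2_type) <= 0:
        raise ValueError("variances must be > 0")
    N = float(n_k.sum())
    n = G * N
    s_a = sigma2 / sigma2_gene
    s_t = sigma2 / sigma2_type
    a = N + s_a
    S = G * np.diag(n_k) + s_t * np.eye(K) - (G / a) * np.outer(n_k, n_k)
    w = v - (u_sum / a) * n_k
    sign, logdetS = np.linalg.slogdet(S)
    sol = np.linalg.solve(S, w)
    q = u_sq / a + float(np.dot(w, sol))
    return float(
        -0.5
        * (
            n * LOG2PI
            + (n - G - K) * np.log(sigma2)
            + G * np.log(sigma2_gene)
            + K * np.log(sigma2_type)
            + G * np.log(a)
            + logdetS
            + (zz - q) / sigma2
        )
    )


def expression_block_loglik(
    Y_sub: np.ndarray,
    types: np.ndarray,
    offsets: np.ndarray,
    sigma2: float,
    sigma2_gene: float,
    sigma2_type: float,
) -> float:
    """Exact Gaussian log marginal of a module's expression block with gene
    and type effects integrated out.

    Parameters
    ----------
    Y_sub : (G_d, N) module expression values.
    types : (N,) type labels in 1..K, every label occupied (empty labels
        are tolerated and contribute nothing).
    offsets : (N,) sampled individual effects r_i, subtracted from every
        gene's row.
    sigma2, sigma2_gene, sigma2_type : error, gene-effect, and type-effect
        variances.
    """
    G, K, n_k, u_sum, u_sq, zz, v = expression_block_suffstats(Y_sub, types, offsets)
    return expression_block_loglik_core(
        G, K, n_k, u_sum, u_sq, zz, v, sigma2, sigma2_gene, sigma2_type
    )


def expression_block_tempered(
    Y_sub: np.ndarray,
    types: np.ndarray,
    offsets: np.ndarray,
    sigma2: float,
    sigma2_gene: float,
    sigma2_type: float,
    beta: float,
) -> float:
    """Tempered expression block: ``log int [p(Y|a,mu) p(a) p(mu)]^beta
    da dmu``.

    At ``beta = 1`` this equals :func:`expression_block_loglik`.  Powering
    the integrand (rather than the integral) keeps the augmented Gibbs
    updates of the gene/type effects exactly conjugate on every tempered
    chain; the two differ by a beta-dependent normalizing factor that this
    form accounts for exactly.
    """
    G, K, n_k, u_sum, u_sq, zz, v = expression_block_suffstats(Y_sub, types, offsets)
    if G == 0:
        return 0.0
    occ = n_k > 0
    n_k, v = n_k[occ], v[occ]
    K = int(occ.sum())
    N = float(n_k.sum())
    n = G * N
    d = G + K
    s_a = sigma2 / sigma2_gene
    s_t = sigma2 / sigma2_type
    a = N + s_a
    S = G * np.diag(n_k) + s_t * np.eye(K) - (G / a) * np.outer(n_k, n_k)
    w = v - (u_sum / a) * n_k
    _, logdetS = np.linalg.slogdet(S)
    q = u_sq / a + float(w @ np.linalg.solve(S, w))
    logdetP = G * np.log(a) + logdetS
    return float(
        -0.5
        * beta
        * (
            (n + d) * LOG2PI
            + n * np.log(sigma2)
            + G * np.log(sigma2_gene)
            + K * np.log(sigma2_type)
            + (zz - q) / sigma2
        )
        + 0.5 * d * (LOG2PI + np.log(sigma2))
        - 0.5 * d * np.log(beta)
        - 0.5 * logdetP
    )


def dense_expression_covariance(
    G: int, types: np.ndarray, sigma2: float, sigma2_gene: float, sigma2_type: float
) -> np.ndarray:
    """Explicit (G*N) x (G*N) covariance of the expression block, row-major
    in gene then individual.  Test oracle for the collapsed form."""
    types = np.asarray(types)
    N = len(types)
    n = G * N
    cov = sigma2 * np.eye(n)
    gene_of = np.repeat(np.arange(G), N)
    type_of = np.tile(types, G)
    cov += sigma2_gene * (gene_of[:, None] == gene_of[None, :])
    cov += sigma2_type * (type_of[:, None] == type_of[None, :])
    return cov


def type_allocation_log_marginal(n_k: np.ndarray, delta: float) -> float:
    """Collapsed log marginal of an individual-type allocation: the mixture
    weights over the K occupied types carry a symmetric Dirichlet(delta)
    prior, integrated to a Dirichlet-multinomial over the type counts.
    This is the generative model of the latent types themselves; without
    it the number of types would grow without bound on pure noise."""
    n_k = np.asarray(n_k)
    n_k = n_k[n_k > 0]
    K = len(n_k)
    N = n_k.sum()
    return float(
        gammaln(K * delta)
        - gammaln(K * delta + N)
        + np.sum(gammaln(delta + n_k))
        - K * gammaln(delta)
    )


def inverse_gamma_logpdf(x: float, a: float, b: float) -> float:
    return float(a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(x) - b / x)


def partition_log_prior(state: PartitionState, hp: Hyperparameters, T: np.ndarray) -> float:
    """Exponential complexity prior (unnormalized) on the indicators."""
    total = 0.0
    for d in range(1, state.D + 1):
        K_d = int(state.K[d - 1])
        markers = state.module_markers(d)
        G_d = int((state.gene_indicator == d).sum())
        log_t = float(np.log(T[markers]).sum())
        total -= hp.lambda_K * (K_d - 1) + hp.lambda_M * K_d * log_t + hp.lambda_G * G_d
    return total


def continuous_param_log_prior(state: PartitionState, hp: Hyperparameters) -> float:
    """Log prior density of the sampled (non-collapsed) parameters: the four
    variance components per module and the individual effects r_i."""
    a, b = hp.prior_var_shape, hp.prior_var_scale
    total = 0.0
    for d in range(state.D):
        for j, v in enumerate(state.variance_params[d]):
            if j == 3:
                total += inverse_gamma_logpdf(float(v), hp.prior_r_shape, hp.prior_r_scale)
            else:
                total += inverse_gamma_logpdf(float(v), a, b)
        s2r = float(state.variance_params[d, 3])
        r = state.individual_effects[d]
        total += float(-0.5 * len(r) * (LOG2PI + np.log(s2r)) - 0.5 * np.dot(r, r) / s2r)
    return total


def module_marker_counts(
    state: PartitionState, d: int, geno: GenotypeMatrix
) -> tuple[np.ndarray, int]:
    """K x C genotype-combination count table of module ``d``."""
    markers = state.module_markers(d)
    K = int(state.K[d - 1])
    C = int(np.prod(geno.T[markers])) if len(markers) else 1
    counts = np.zeros((K, C), dtype=np.int64)
    if len(markers):
        combo = np.zeros(geno.n_individuals, dtype=np.int64)
        for m in markers:
            combo = combo * int(geno.T[m]) + geno.codes[m]
        for i in range(geno.n_individuals):
            counts[state.type_indicator[d - 1, i] - 1, combo[i]] += 1
    else:
        t = state.type_indicator[d - 1]
        for k in range(K):
            counts[k, 0] = int((t == k + 1).sum())
    return counts, C


def log_posterior(
    state: PartitionState,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
) -> float:
    """Full (unnormalized) log posterior of one partition state: module
    expression and marker blocks, null gene/marker marginals, the partition
    prior, and the prior densities of the sampled continuous parameters."""
    gp = GaussianPriorSpec(hp.prior_mean_scale, hp.prior_var_shape, hp.prior_var_scale)
    dir_spec = DirichletSpec(hp.dirichlet_conc)
    total = partition_log_prior(state, hp, geno.T)
    total += continuous_param_log_prior(state, hp)
    for g in np.where(state.gene_indicator == 0)[0]:
        total += null_gene_loglik(expr.values[g], gp)
    for m in np.where(state.marker_indicator == 0)[0]:
        counts = np.bincount(geno.codes[m], minlength=int(geno.T[m]))
        total += null_marker_loglik(counts, dir_spec)
    for d in range(1, state.D + 1):
        counts_k = np.bincount(state.type_indicator[d - 1] - 1, minlength=int(state.K[d - 1]))
        total += type_allocation_log_marginal(counts_k, hp.type_conc)
        genes = state.module_genes(d)
        if len(genes):
            s2, s2g, s2t, _ = state.variance_params[d - 1]
            total += expression_block_loglik(
                expr.values[genes],
                state.type_indicator[d - 1],
                state.individual_effects[d - 1],
                float(s2),
                float(s2g),
                float(s2t),
            )
        if len(state.module_markers(d)):
            counts, _ = module_marker_counts(state, d, geno)
            total += marker_block_loglik(counts, dir_spec)
    return float(total)


def tempered_log_posterior(
    state: PartitionState,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
    beta: float,
) -> float:
    """Log density targeted by a tempered chain at inverse temperature
    ``beta``: the collapsed likelihood and indicator prior are raised to
    ``beta`` (the expression block via :func:`expression_block_tempered`);
    the continuous-parameter priors are untempered.  ``beta = 1`` recovers
    :func:`log_posterior` exactly."""
    gp = GaussianPriorSpec(hp.prior_mean_scale, hp.prior_var_shape, hp.prior_var_scale)
    dir_spec = DirichletSpec(hp.dirichlet_conc)
    total = beta * partition_log_prior(state, hp, geno.T)
    total += continuous_param_log_prior(state, hp)
    for g in np.where(state.gene_indicator == 0)[0]:
        total += beta * null_gene_loglik(expr.values[g], gp)
    for m in np.where(state.marker_indicator == 0)[0]:
        counts = np.bincount(geno.codes[m], minlength=int(geno.T[m]))
        total += beta * null_marker_loglik(counts, dir_spec)
    for d in range(1, state.D + 1):
        counts_k = np.bincount(state.type_indicator[d - 1] - 1, minlength=int(state.K[d - 1]))
        total += beta * type_allocation_log_marginal(counts_k, hp.type_conc)
        genes = state.module_genes(d)
        if len(genes):
            s2, s2g, s2t, _ = state.variance_params[d - 1]
            total += expression_block_tempered(
                expr.values[genes],
                state.type_indicator[d - 1],
                state.individual_effects[d - 1],
                float(s2),
                float(s2g),
                float(s2t),
                beta,
            )
        if len(state.module_markers(d)):
            counts, _ = module_marker_counts(state, d, geno)
            total += beta * marker_block_loglik(counts, dir_spec)
    return float(total)
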