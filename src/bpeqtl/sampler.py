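"""MCMC engine: Gibbs/Metropolis kernels over indicators, reversible-jump
split-merge over individual types, and parallel tempering.

``run_mcmc`` drives the numba inner loops in ``_kernels``; the module also
provides pure-Python kernel operations on :class:`PartitionState` (used by
the exactness tests, which enumerate tiny state spaces) built on the same
tempered target, ``marginals.tempered_log_posterior``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels as kern
from .data import (
    ExpressionMatrix,
    GenotypeMatrix,
    Hyperparameters,
    PartitionState,
    initial_state,
)
from .marginals import (
    DirichletSpec,
    GaussianPriorSpec,
    null_gene_loglik,
    null_marker_loglik,
    tempered_log_posterior,
)


@dataclass
class SamplerConfig:
    """Run-time settings of the sampler.

    ``temperatures`` is the inverse-temperature ladder (beta = 1 first,
    strictly decreasing); by default a geometric ladder with ratio 0.85,
    which puts adjacent-swap acceptance in the targeted 0.15-0.3 range on
    the simulated designs.
    """

    n_iterations: int = 2000
    burn_in: int = 500
    thinning: int = 5
    n_chains: int = 1
    temperatures: Optional[Sequence[float]] = None
    seed: int = 0
    ld_r_threshold: float = 0.9
    swap_interval: int = 10
    sample_continuous: bool = True
    init_frac_assigned: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 < self.ld_r_threshold <= 1:
            raise ValueError("ld_r_threshold must be in (0, 1]")
        if self.temperatures is None:
            self.temperatures = [0.85**k for k in range(self.n_chains)]
        self.temperatures = [float(b) for b in self.temperatures]
        if len(self.temperatures) != self.n_chains:
            raise ValueError("temperature ladder length must equal n_chains")
        if abs(self.temperatures[0] - 1.0) > 1e-12:
            raise ValueError("ladder must start at beta = 1")
        if any(b2 >= b1 for b1, b2 in zip(self.temperatures, self.temperatures[1:])):
            raise ValueError("ladder must be strictly decreasing")


@dataclass(frozen=True)
class ExclusionSet:
    """Unordered marker pairs forbidden from sharing a module."""

    pairs: frozenset

    def __contains__(self, pair) -> bool:
        a, b = pair
        return frozenset((a, b)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def matrix(self, n_markers: int) -> np.ndarray:
        out = np.zeros((n_markers, n_markers), dtype=np.uint8)
        for p in self.pairs:
            a, b = tuple(p)
            out[a, b] = out[b, a] = 1
        return out


def build_ld_exclusion(geno: GenotypeMatrix, r_threshold: float) -> ExclusionSet:
    """Marker pairs whose absolute Pearson correlation of genotype codes
    exceeds ``r_threshold``; monomorphic markers join no pair."""
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    codes = geno.codes.astype(np.float64)
    sd = codes.std(axis=1)
    poly = sd > 0
    pairs = set()
    if poly.sum() >= 2:
        sub = np.where(poly)[0]
        corr = np.corrcoef(codes[sub])
        ii, jj = np.where(np.abs(np.triu(corr, k=1)) > r_threshold)
        for i, j in zip(ii, jj):
            pairs.add(frozenset((int(sub[i]), int(sub[j]))))
    return ExclusionSet(frozenset(pairs))


@dataclass
class SampleTrace:
    """Thinned post-burn-in snapshots plus the per-iteration log-posterior
    series of the cold chain and swap-acceptance counters."""

    gene_snapshots: np.ndarray  # S x G
    marker_snapshots: np.ndarray  # S x M
    type_snapshots: np.ndarray  # S x D x N
    K_snapshots: np.ndarray  # S x D
    log_posterior: np.ndarray  # n_iterations
    swap_attempts: np.ndarray  # n_chains - 1
    swap_accepts: np.ndarray
    config: SamplerConfig = None
    gene_ids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=list)

    @property
    def n_snapshots(self) -> int:
        return self.gene_snapshots.shape[0]

    def swap_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.swap_accepts / np.maximum(self.swap_attempts, 1)


class _Chain:
    """One tempered chain: state arrays plus the sampler caches."""

    def __init__(self, state: PartitionState, data, hp: Hyperparameters, beta: float):
        Y = data["Y"]
        D = state.D
        N = Y.shape[1]
        maxK = hp.max_types
        Cmax = int(data["T"].max()) ** hp.max_markers_per_module
        self.beta = beta
        self.gene_ind = state.gene_indicator.astype(np.int64)
        self.marker_ind = state.marker_indicator.astype(np.int64)
        self.types = state.type_indicator.astype(np.int64)
        self.K = state.K.astype(np.int64)
        self.r = state.individual_effects.astype(np.float64)
        self.var = state.variance_params.astype(np.float64)
        self.colsum = np.zeros((D, N))
        self.Gd = np.zeros(D, dtype=np.int64)
        self.sumy = np.zeros(D)
        self.sumy2 = np.zeros(D)
        self.sumsq = np.zeros(D)
        self.rsum = np.zeros(D)
        self.rsumsq = np.zeros(D)
        self.rc = np.zeros(D)
        self.vcol = np.zeros((D, maxK))
        self.rtyp = np.zeros((D, maxK))
        self.n_k = np.zeros((D, maxK), dtype=np.int64)
        self.combo = np.zeros((D, N), dtype=np.int64)
        self.Cmod = np.ones(D, dtype=np.int64)
        self.Mcnt = np.zeros(D, dtype=np.int64)
        self.slT = np.zeros(D)
        self.ccounts = np.zeros((D, maxK, Cmax), dtype=np.int64)
        self.tb = np.zeros(D)
        self.mb = np.zeros(D)
        self.nulls = np.zeros(2)
        self.rebuild(data, hp)

    def rebuild(self, data, hp: Hyperparameters) -> None:
        kern._rebuild_all(
            data["Y"], data["rowsum"], data["rowsumsq"], data["X"], data["T"],
            data["logT"], data["nullg"], data["nullm"],
            self.gene_ind, self.marker_ind, self.types, self.K, self.r, self.var,
            self.colsum, self.Gd, self.sumy, self.sumy2, self.sumsq,
            self.rsum, self.rsumsq, self.rc, self.vcol, self.rtyp, self.n_k,
            self.combo, self.Cmod, self.Mcnt, self.slT, self.ccounts,
            self.tb, self.mb, self.nulls,
            hp.dirichlet_conc, self.beta,
        )

    def state_arrays(self):
        return (self.gene_ind, self.marker_ind, self.types, self.K, self.r, self.var)

    def cache_arrays(self):
        return (
            self.colsum, self.Gd, self.sumy, self.sumy2, self.sumsq,
            self.rsum, self.rsumsq, self.rc, self.vcol, self.rtyp, self.n_k,
            self.combo, self.Cmod, self.Mcnt, self.slT, self.ccounts,
            self.tb, self.mb, self.nulls,
        )

    def sweep(self, rng, data, hp: Hyperparameters, sample_continuous: bool) -> None:
        kern._sweep(
            rng, data["Y"], data["rowsum"], data["rowsumsq"], data["X"], data["T"],
            data["logT"], data["nullg"], data["nullm"], data["excl"],
            data["mw"], data["mcum"], data["pw"], data["pcum"], data["pi"], data["pj"],
            *self.state_arrays(), *self.cache_arrays(),
            hp.dirichlet_conc, hp.type_conc, hp.prior_var_shape, hp.prior_var_scale,
            hp.prior_r_shape, hp.prior_r_scale,
            hp.lambda_K, hp.lambda_M, hp.lambda_G,
            hp.max_markers_per_module, hp.max_types, self.beta,
            sample_continuous,
        )

    def log_target(self, hp: Hyperparameters, beta: float) -> float:
        return kern._chain_logpost(
            *self.state_arrays(), *self.cache_arrays(),
            hp.dirichlet_conc, hp.type_conc, hp.prior_var_shape, hp.prior_var_scale,
            hp.prior_r_shape, hp.prior_r_scale,
            hp.lambda_K, hp.lambda_M, hp.lambda_G, beta,
        )

    def refresh_tb(self, hp: Hyperparameters) -> None:
        for idx in range(self.types.shape[0]):
            self.tb[idx] = kern._tb_module(
                idx, self.Gd, self.sumy, self.sumy2, self.sumsq,
                self.rsum, self.rsumsq, self.rc, self.vcol, self.rtyp,
                self.n_k, self.K, self.var, self.beta,
            )


PROPOSAL_TEMPERATURE = 2.0  # softmax scale on Fisher-z association scores


N_PROPOSAL_PCS = 20  # expression principal components used to score loci


def _association_weights(Y: np.ndarray, X: np.ndarray):
    """Data-driven proposal weights for marker and marker-pair moves.

    Module structure concentrates in the leading principal components of
    the (gene-standardized) expression matrix, so each marker is scored
    by its best squared correlation with a top PC, and each marker pair
    by the best R^2 of its four-cell genotype factor on a top PC — which
    captures marginal, mixed and purely epistatic pairs alike.  A softmax
    of the Fisher-z-transformed scores concentrates birth proposals on
    plausibly associated loci.  The weights depend only on the data,
    never on the sampler state, so proposal densities stay exact.
    """
    G, N = Y.shape
    M = X.shape[0]
    sd = Y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Yz = (Y - Y.mean(axis=1, keepdims=True)) / sd
    n_pc = min(N_PROPOSAL_PCS, G, N)
    _, _, Vt = np.linalg.svd(Yz, full_matrices=False)
    pcs = Vt[:n_pc]
    pcs = (pcs - pcs.mean(axis=1, keepdims=True))
    pcs /= np.maximum(pcs.std(axis=1, keepdims=True), 1e-12)
    zcap = 10.0
    scale = math.sqrt(max(N - 3, 1))

    def scores_to_w(best_r):
        z = np.arctanh(np.clip(best_r, 0.0, 0.99)) * scale
        w = np.exp(PROPOSAL_TEMPERATURE * np.minimum(z, zcap))
        return w / w.sum()

    Xf = X.astype(np.float64)
    sdx = Xf.std(axis=1, keepdims=True)
    sdx[sdx == 0] = 1.0
    Xz = (Xf - Xf.mean(axis=1, keepdims=True)) / sdx
    best_single = np.abs(Xz @ pcs.T / N).max(axis=1)
    mw = scores_to_w(best_single)

    n_pairs = M * (M - 1) // 2
    pi = np.empty(n_pairs, dtype=np.int64)
    pj = np.empty(n_pairs, dtype=np.int64)
    k = 0
    for i in range(M):
        cnt = M - 1 - i
        pi[k : k + cnt] = i
        pj[k : k + cnt] = np.arange(i + 1, M)
        k += cnt
    best_pair = np.zeros(n_pairs)
    chunk = 1024
    for s in range(0, n_pairs, chunk):
        e = min(s + chunk, n_pairs)
        cells = X[pi[s:e]] * 2 + X[pj[s:e]]  # (chunk, N), binary markers
        acc = np.zeros((e - s, pcs.shape[0]))
        for c in range(4):
            mask = (cells == c).astype(np.float64)
            n_c = mask.sum(axis=1)
            n_c[n_c == 0] = 1.0
            sums = mask @ pcs.T  # (chunk, n_pc)
            acc += (sums**2) / n_c[:, None] / N
        best_pair[s:e] = np.sqrt(np.clip(acc.max(axis=1), 0.0, 0.99))
    pwf = scores_to_w(best_pair)
    pw = np.zeros((M, M))
    pw[pi, pj] = pwf
    pw[pj, pi] = pwf
    return {
        "mw": mw,
        "mcum": np.cumsum(mw),
        "pw": pw,
        "pcum": np.cumsum(pwf),
        "pi": pi,
        "pj": pj,
    }


def _prepare_data(expr: ExpressionMatrix, geno: GenotypeMatrix,
                  hp: Hyperparameters, excl: ExclusionSet):
    Y = np.ascontiguousarray(expr.values, dtype=np.float64)
    X = np.ascontiguousarray(geno.codes, dtype=np.int64)
    gp = GaussianPriorSpec(hp.prior_mean_scale, hp.prior_var_shape, hp.prior_var_scale)
    dspec = DirichletSpec(hp.dirichlet_conc)
    nullg = np.array([null_gene_loglik(Y[g], gp) for g in range(Y.shape[0])])
    nullm = np.array([
        null_marker_loglik(np.bincount(X[m], minlength=int(geno.T[m])), dspec)
        for m in range(X.shape[0])
    ])
    data = {
        "Y": Y,
        "rowsum": Y.sum(axis=1),
        "rowsumsq": (Y * Y).sum(axis=1),
        "X": X,
        "T": geno.T.astype(np.int64),
        "logT": np.log(geno.T.astype(np.float64)),
        "nullg": nullg,
        "nullm": nullm,
        "excl": excl.matrix(X.shape[0]),
    }
    data.update(_association_weights(Y, X))
    return data


def run_mcmc(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
    cfg: SamplerConfig,
    exclusion: Optional[ExclusionSet] = None,
    initial: Optional[PartitionState] = None,
    progress: Optional[callable] = None,
) -> SampleTrace:
    """Run the full sampler and return the cold chain's trace.

    Identical (data, hyperparameters, config) give an identical trace.
    """
    if expr.n_individuals != geno.n_individuals:
        raise ValueError("expression and genotype individual counts differ")
    rng = np.random.default_rng(cfg.seed)
    if exclusion is None:
        exclusion = build_ld_exclusion(geno, cfg.ld_r_threshold)
    data = _prepare_data(expr, geno, hp, exclusion)
    G, N = data["Y"].shape
    M = data["X"].shape[0]
    chains = []
    for c, beta in enumerate(cfg.temperatures):
        st = initial.copy() if initial is not None else initial_state(
            G, N, M, hp, rng, cfg.init_frac_assigned
        )
        chains.append(_Chain(st, data, hp, beta))
    n_save = max(0, (cfg.n_iterations - cfg.burn_in) // cfg.thinning)
    gene_snap = np.zeros((n_save, G), dtype=np.int16)
    marker_snap = np.zeros((n_save, M), dtype=np.int16)
    type_snap = np.zeros((n_save, hp.D, N), dtype=np.int8)
    K_snap = np.zeros((n_save, hp.D), dtype=np.int8)
    logpost = np.zeros(cfg.n_iterations)
    swap_att = np.zeros(max(cfg.n_chains - 1, 0), dtype=np.int64)
    swap_acc = np.zeros(max(cfg.n_chains - 1, 0), dtype=np.int64)
    s = 0
    for it in range(cfg.n_iterations):
        for ch in chains:
            ch.sweep(rng, data, hp, cfg.sample_continuous)
        if cfg.n_chains > 1 and (it + 1) % cfg.swap_interval == 0:
            for p in range(cfg.n_chains - 1):
                ci, cj = chains[p], chains[p + 1]
                bi, bj = cfg.temperatures[p], cfg.temperatures[p + 1]
                swap_att[p] += 1
                lp_ii = ci.log_target(hp, bi)
                lp_jj = cj.log_target(hp, bj)
                lp_ij = ci.log_target(hp, bj)
                lp_ji = cj.log_target(hp, bi)
                log_acc = (lp_ji + lp_ij) - (lp_ii + lp_jj)
                if math.log(rng.random()) < log_acc:
                    swap_acc[p] += 1
                    _swap_chain_payload(ci, cj)
                    ci.refresh_tb(hp)
                    cj.refresh_tb(hp)
        cold = chains[0]
        logpost[it] = cold.log_target(hp, 1.0)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == cfg.thinning - 1:
            gene_snap[s] = cold.gene_ind
            marker_snap[s] = cold.marker_ind
            type_snap[s] = cold.types
            K_snap[s] = cold.K
            s += 1
        if progress is not None and (it + 1) % 500 == 0:
            progress(it + 1, float(logpost[it]))
    return SampleTrace(
        gene_snap[:s], marker_snap[:s], type_snap[:s], K_snap[:s],
        logpost, swap_att, swap_acc, cfg,
        list(expr.gene_ids), list(geno.marker_ids),
    )


def _swap_chain_payload(ci: _Chain, cj: _Chain) -> None:
    """Exchange the full state + caches of two chains (betas stay put)."""
    for name in (
        "gene_ind", "marker_ind", "types", "K", "r", "var",
        "colsum", "Gd", "sumy", "sumy2", "sumsq", "rsum", "rsumsq", "rc",
        "vcol", "rtyp", "n_k", "combo", "Cmod", "Mcnt", "slT", "ccounts",
        "tb", "mb", "nulls",
    ):
        a, b = getattr(ci, name), getattr(cj, name)
        setattr(ci, name, b)
        setattr(cj, name, a)


# ----------------------------------------------------------------------
# PartitionState-level kernels (reference implementations used in tests)
# ----------------------------------------------------------------------


def gene_full_conditional(
    g: int,
    state: PartitionState,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
    beta: float = 1.0,
) -> np.ndarray:
    """Full-conditional probabilities of gene ``g``'s indicator over
    {0, ..., D} under the tempered target."""
    logw = np.empty(hp.D + 1)
    work = state.copy()
    for c in range(hp.D + 1):
        work.gene_indicator[g] = c
        logw[c] = tempered_log_posterior(work, expr, geno, hp, beta)
    logw -= logw.max()
    p = np.exp(logw)
    return p / p.sum()


def gibbs_update_gene(g, state, expr, geno, hp, beta, rng) -> PartitionState:
    p = gene_full_conditional(g, state, expr, geno, hp, beta)
    state.gene_indicator[g] = rng.choice(hp.D + 1, p=p)
    return state


def marker_transition_probs(
    m: int,
    state: PartitionState,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
    excl: ExclusionSet,
    beta: float = 1.0,
) -> dict[int, float]:
    """Exact transition distribution of the marker-m MH kernel (uniform
    reassignment proposal; exclusion and capacity violations rejected)."""
    d0 = int(state.marker_indicator[m])
    lp0 = tempered_log_posterior(state, expr, geno, hp, beta)
    probs = {d0: 0.0}
    work = state.copy()
    for d1 in range(hp.D + 1):
        if d1 == d0:
            continue
        ok = True
        if d1 > 0:
            members = [int(x) for x in np.where(state.marker_indicator == d1)[0]]
            if len(members) >= hp.max_markers_per_module:
                ok = False
            if any((m, m2) in excl for m2 in members):
                ok = False
        if not ok:
            acc = 0.0
        else:
            work.marker_indicator[m] = d1
            acc = min(1.0, math.exp(beta * 0.0 + (
                tempered_log_posterior(work, expr, geno, hp, beta) - lp0
            )))
            work.marker_indicator[m] = d0
        probs[d1] = acc / hp.D
    probs[d0] = 1.0 - sum(v for k, v in probs.items() if k != d0)
    return probs


def update_marker(m, state, expr, geno, hp, excl, beta, rng) -> PartitionState:
    probs = marker_transition_probs(m, state, expr, geno, hp, excl, beta)
    dests = sorted(probs)
    state.marker_indicator[m] = rng.choice(dests, p=[probs[d] for d in dests])
    return state


def individual_full_conditional(
    d: int,
    i: int,
    state: PartitionState,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
    beta: float = 1.0,
) -> tuple[list[PartitionState], np.ndarray]:
    """Candidate states and probabilities for resampling individual ``i``'s
    type in module ``d``.  The full conditional ranges over set partitions:
    i may join any block of the remaining individuals or open a fresh
    singleton type (states are canonicalized; an emptied label compacts)."""
    K_d = int(state.K[d - 1])
    was_singleton = int((state.type_indicator[d - 1] == state.type_indicator[d - 1, i]).sum()) == 1
    labels = list(range(1, K_d + 1))
    if not was_singleton and K_d < hp.max_types:
        labels.append(K_d + 1)
    cands, logw = [], []
    for k in labels:
        work = state.copy()
        work.type_indicator[d - 1, i] = k
        if k == K_d + 1:
            work.K[d - 1] = K_d + 1
        work.canonicalize_types(d)
        cands.append(work)
        logw.append(tempered_log_posterior(work, expr, geno, hp, beta))
    logw = np.array(logw)
    logw -= logw.max()
    p = np.exp(logw)
    return cands, p / p.sum()


def gibbs_update_individual(i, d, state, expr, geno, hp, beta, rng) -> PartitionState:
    cands, p = individual_full_conditional(d, i, state, expr, geno, hp, beta)
    return cands[rng.choice(len(cands), p=p)]


SPLIT_MARKER_FRAC = kern.SPLIT_MARKER_FRAC
SPLIT_EXPR_FRAC = kern.SPLIT_EXPR_FRAC


def _expr_key(state: PartitionState, expr: ExpressionMatrix, d: int) -> np.ndarray:
    """Per-individual module expression evidence used to order split cuts."""
    genes = state.module_genes(d)
    G = len(genes)
    return expr.values[genes].sum(axis=0) - G * state.individual_effects[d - 1]


def _expr_cut_density(members: np.ndarray, side: np.ndarray, key: np.ndarray) -> float:
    order = sorted(range(len(members)), key=lambda a: (key[members[a]], members[a]))
    flags = side[order]
    changes = int(np.sum(flags[1:] != flags[:-1]))
    return 1.0 / (len(members) - 1.0) if changes == 1 else 0.0


def _marker_split_density(geno: GenotypeMatrix, members: np.ndarray, side: np.ndarray) -> float:
    """Total proposal density of the marker-guided route for the unordered
    split of ``members`` into (side, ~side): each (marker, code) pair whose
    genotype pattern induces exactly this split contributes 1/(M * T_m)."""
    M = geno.n_markers
    S = 0.0
    for m in range(M):
        codes = geno.codes[m, members]
        for a, b in ((codes[side], codes[~side]), (codes[~side], codes[side])):
            u = np.unique(a)
            if len(u) == 1 and not np.any(b == u[0]):
                S += 1.0 / (M * int(geno.T[m]))
    return S


def split_merge_types(d, state, expr, geno, hp, beta, rng) -> PartitionState:
    """One split-merge proposal on module ``d`` (reference implementation,
    identical proposal/acceptance arithmetic to the compiled path)."""
    K_d = int(state.K[d - 1])
    rho_m, rho_e = SPLIT_MARKER_FRAC, SPLIT_EXPR_FRAC
    rho_r = 1.0 - rho_m - rho_e
    key = _expr_key(state, expr, d)
    lp0 = tempered_log_posterior(state, expr, geno, hp, beta)
    if rng.random() < 0.5:
        if K_d >= hp.max_types:
            return state
        k = int(rng.integers(1, K_d + 1))
        members = np.where(state.type_indicator[d - 1] == k)[0]
        route = rng.random()
        if route < rho_m:
            m = int(rng.integers(geno.n_markers))
            c = int(rng.integers(int(geno.T[m])))
            side = geno.codes[m, members] == c
        elif route < rho_m + rho_e:
            if len(members) < 2:
                return state
            order = sorted(range(len(members)), key=lambda a: (key[members[a]], members[a]))
            cut = int(rng.integers(1, len(members)))
            side = np.zeros(len(members), dtype=bool)
            side[[order[a] for a in range(cut, len(members))]] = True
        else:
            side = rng.random(len(members)) < 0.5
        if side.sum() in (0, len(members)):
            return state
        q_split = (
            rho_r * 2.0 ** (1.0 - len(members))
            + rho_m * _marker_split_density(geno, members, side)
            + rho_e * _expr_cut_density(members, side, key)
        )
        work = state.copy()
        work.type_indicator[d - 1, members[side]] = K_d + 1
        work.K[d - 1] = K_d + 1
        lp1 = tempered_log_posterior(work, expr, geno, hp, beta)
        logq = math.log(K_d) - math.log(q_split) - math.log((K_d + 1) * K_d / 2.0)
        if math.log(rng.random()) < (lp1 - lp0) + logq:
            work.canonicalize_types(d)
            return work
        return state
    else:
        if K_d <= 1:
            return state
        k1, k2 = sorted(rng.choice(np.arange(1, K_d + 1), size=2, replace=False))
        work = state.copy()
        sel = work.type_indicator[d - 1] == k2
        members = np.where(
            (state.type_indicator[d - 1] == k1) | (state.type_indicator[d - 1] == k2)
        )[0]
        side = state.type_indicator[d - 1, members] == k2
        n_merged = len(members)
        work.type_indicator[d - 1, sel] = k1
        work.canonicalize_types(d)
        lp1 = tempered_log_posterior(work, expr, geno, hp, beta)
        q_split_rev = (
            rho_r * 2.0 ** (1.0 - n_merged)
            + rho_m * _marker_split_density(geno, members, side)
            + rho_e * _expr_cut_density(members, side, key)
        )
        logq = math.log(K_d * (K_d - 1) / 2.0) - math.log(K_d - 1) + math.log(q_split_rev)
        if math.log(rng.random()) < (lp1 - lp0) + logq:
            return work
        return state


def update_continuous(d, state, expr, geno, hp, beta, rng) -> PartitionState:
    """Gibbs refresh of module ``d``'s continuous parameters (reference
    implementation of the augmented conjugate draws)."""
    idx = d - 1
    N = expr.n_individuals
    genes = state.module_genes(d)
    G = len(genes)
    K_d = int(state.K[idx])
    s2, s2g, s2t, s2r = (float(x) for x in state.variance_params[idx])
    a0, b0 = hp.prior_var_shape, hp.prior_var_scale
    types = state.type_indicator[idx]
    r = state.individual_effects[idx]
    if G > 0:
        Z = expr.values[genes] - r[None, :]
        n_k = np.bincount(types - 1, minlength=K_d).astype(np.float64)
        P = np.zeros((G + K_d, G + K_d))
        P[:G, :G] = (N + s2 / s2g) * np.eye(G)
        P[:G, G:] = n_k[None, :]
        P[G:, :G] = n_k[:, None]
        P[G:, G:] = G * np.diag(n_k) + (s2 / s2t) * np.eye(K_d)
        rhs = np.concatenate([
            Z.sum(axis=1),
            [Z[:, types == k + 1].sum() for k in range(K_d)],
        ])
        mean = np.linalg.solve(P, rhs)
        L = np.linalg.cholesky(P)
        x = mean + math.sqrt(s2 / beta) * np.linalg.solve(L.T, rng.standard_normal(G + K_d))
        alpha, mu = x[:G], x[G:]
        resid_i = expr.values[genes].sum(axis=0) - alpha.sum() - G * mu[types - 1]
        prec = beta * G / s2 + 1.0 / s2r
        r[:] = (beta / s2) * resid_i / prec + rng.standard_normal(N) / math.sqrt(prec)
        E = expr.values[genes] - alpha[:, None] - mu[types - 1][None, :] - r[None, :]
        ss = float((E * E).sum())
        state.variance_params[idx, 0] = (b0 + 0.5 * beta * ss) / rng.gamma(
            a0 + 0.5 * beta * G * N
        )
        state.variance_params[idx, 1] = (b0 + 0.5 * beta * float(alpha @ alpha)) / rng.gamma(
            a0 + 0.5 * beta * G
        )
        state.variance_params[idx, 2] = (b0 + 0.5 * beta * float(mu @ mu)) / rng.gamma(
            a0 + 0.5 * beta * K_d
        )
    else:
        state.variance_params[idx, :3] = b0 / rng.gamma(a0, size=3)
        r[:] = rng.normal(0.0, math.sqrt(s2r), size=N)
    state.variance_params[idx, 3] = (hp.prior_r_scale + 0.5 * float(r @ r)) / rng.gamma(
        hp.prior_r_shape + 0.5 * N
    )
    return state


def tempering_swap(
    states: list[PartitionState],
    betas: Sequence[float],
    pair: tuple[int, int],
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    hp: Hyperparameters,
    rng,
) -> tuple[list[PartitionState], bool]:
    """Propose exchanging the states of two adjacent tempered chains."""
    i, j = pair
    if abs(i - j) != 1:
        raise ValueError("only adjacent chains may swap")
    lp_ii = tempered_log_posterior(states[i], expr, geno, hp, betas[i])
    lp_jj = tempered_log_posterior(states[j], expr, geno, hp, betas[j])
    lp_ij = tempered_log_posterior(states[i], expr, geno, hp, betas[j])
    lp_ji = tempered_log_posterior(states[j], expr, geno, hp, betas[i])
    if math.log(rng.random()) < (lp_ji + lp_ij) - (lp_ii + lp_jj):
        states[i], states[j] = states[j], states[i]
        return states, True
    return states, False


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Normalized autocorrelation of a scalar series up to ``max_lag``."""
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.zeros(max_lag + 1)
    return np.array([
        float(x[: len(x) - lag] @ x[lag:]) / denom for lag in range(max_lag + 1)
    ])
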