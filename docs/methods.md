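# Methods

## The model

`bpeqtl` jointly partitions `G` expression traits ("genes"), `M` genetic
markers and `N` individuals of a segregating population into `D` non-null
*modules* plus a null component. A module is a set of co-expressed genes
together with the set of markers whose joint genotype explains their
variation; the link between the two sides is a latent **individual type**
`k = 1..K_d` — a class label for each individual, conditional on which the
module's expression traits and marker genotypes are independent. One type
typically corresponds to one (or a merged group of) genotype combination(s)
of the module's markers, so the construction expresses both pleiotropy
(many genes, one locus set) and epistasis (type patterns that no single
locus explains).

Within module `d` expression follows the ANOVA decomposition

    y_{g,i} = alpha_g + mu_{k(i)} + r_i + eps_{g,i},

with gene effects `alpha_g ~ N(0, sigma_a^2)`, type effects
`mu_k ~ N(0, sigma_t^2)` shared across the module's genes, individual
effects `r_i ~ N(0, sigma_r^2)` and errors `eps ~ N(0, sigma^2)`.
`alpha` and `mu` are integrated out analytically (the collapsed block is a
Gaussian whose covariance adds same-gene and same-type blocks to
`sigma^2 I`; we evaluate it through a Woodbury identity reduced to a
`K_d x K_d` solve). `r_i` and the four variance components cannot be
integrated jointly with the discrete moves and are sampled by Gibbs.

The module's markers are modelled jointly: the genotype combination of
individual `i` over the `M_d` markers (one of `C = prod T_m` cells) is
multinomial with a type-specific frequency vector carrying a symmetric
Dirichlet prior (collapsed to Dirichlet-multinomial marginals). Null genes
follow a normal-inverse-gamma collapsed marginal (Student-t); null markers
independent Dirichlet-multinomials.

Two prior pieces control complexity:

- an exponential penalty on the indicators,
  `log prior = -sum_d [lambda_K (K_d - 1) + lambda_M K_d M_d log T
  + lambda_G G_d]`;
- a collapsed Dirichlet-multinomial over the type allocation itself
  (mixture weights over the `K_d` types with symmetric concentration
  `type_conc`). This term is implied by any generative reading of the
  latent individual type; without it the combinatorial multiplicity of
  labelings drives `K_d` to its maximum on pure noise.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `D` | user | number of non-null modules; pick ~1.5x the expected count, spares stay empty |
| `dirichlet_conc` | 1.0 | Dirichlet concentration over genotype-combination cells |
| `type_conc` | 1.0 | Dirichlet concentration over type proportions |
| `lambda_K` | 2.0 | penalty per extra individual type |
| `lambda_M` | 5.0 | penalty per marker, scaled by `K_d log T` |
| `lambda_G` | 6.0 | penalty per module gene |
| `prior_var_shape/scale` | 1, 1 | IG prior of sigma^2, sigma_a^2, sigma_t^2 |
| `prior_r_shape/scale` | 50, 0.5 | IG prior of sigma_r^2 (pinned near 0.01) |
| `max_markers_per_module` | 3 | bounds the T^{M_d} count tables |
| `max_types` | 9 | two to nine types cover up to two triallelic loci |

Calibration notes (all decided on *null* data — pure-noise expression and
independent markers — never on detection benchmarks):

- `lambda_G = 6`. The null component's NIG-collapsed marginal is 2-3 nats
  weaker per (standardized) gene than the module Gaussian with its sampled
  error variance, and the advantage is multiplied by the number of modules
  a gene could join. Six nats keeps noise-gene occupancy at ~5% even with
  `D = 12`.
- `lambda_M = 5`. Chance pairwise correlations among independent markers at
  `N = 120` are worth up to ~7 nats to a cherry-picking sampler; five nats
  per marker (times `K_d log T`) suppresses them in gene-bearing modules
  while leaving true markers (tens of nats of Dirichlet-multinomial gain)
  unaffected.
- `sigma_r^2` prior pinned near 0.01. After quantile normalization and
  per-gene standardization, per-individual offsets are small by
  construction. A loose prior lets the `N` free individual effects absorb
  the latent-type signal before any types exist (a ridge between `r_i` and
  `mu_k` that freezes `K_d = 1`); the informative prior reflects the
  post-normalization scale and removes the ridge.

## MCMC

A systematic sweep updates: every gene indicator (collapsed Gibbs over
`{0..D}`), every marker indicator (Metropolis-Hastings with uniform
reassignment plus per-module swap and null-exchange moves), every
individual's type per module (collapsed Gibbs whose candidate set ranges
over set partitions: join any existing type *or open a fresh singleton* —
omitting the singleton makes the conditional incomplete and blocks growth
of `K_d`), a reversible-jump split-merge per module, joint marker moves
(below), and the conjugate refresh of `(alpha, mu) -> r -> variances`
(partially collapsed Gibbs: the marginalized indicator updates always
precede the exact joint draw of the collapsed effects).

Split proposals mix three allocation routes, with the acceptance ratio
using the exact mixture density: uniform random (the textbook move),
along a random marker's genotype, and a contiguous cut of the type in
module-expression order. Merges invert them.

Because a type partition and the marker that defines it only pay off
*jointly* (each alone is 20-80 nats uphill against the allocation prior),
three joint moves carry most mixing on realistic data:

- **marker birth/death** — add a null marker and split one type along its
  genotype; reverse removes a marker and merges a pair the marker
  separates exactly;
- **marker-pair birth/death** — add two null markers and split a type
  along their genotype-agreement diagonal (the bipartition a purely
  epistatic pair induces; it tolerates the type impurity real
  heritabilities produce); reverse removes the pair and merges;
- **swap-with-split** — exchange an in-module marker for a null marker
  while splitting along the incoming one, so a chance-correlated squatter
  cannot block the truly associated marker's slot;
- **reallocation moves** — change the module's marker set (add one
  marker, add a pair, or swap a pair in for two evicted members) while
  re-proposing the *entire* type partition by sequential allocation.  The
  allocation mixes two routes with the exact mixture density used in the
  acceptance ratio: an informed route whose per-individual weights follow
  the Dirichlet-multinomial predictive of the genotype combination under
  the proposed marker set (producing genotype-cell partitions), and a
  plain size-based route under which coarse partitions have high density
  (otherwise regenerating an unstructured partition in the reverse
  direction would be astronomically unlikely and detailed balance would
  veto every forward jump).  Forward partitions are sampled; reverse
  densities are obtained by replaying the current partition through the
  same machinery.

Incoming markers and pairs are proposed from a *data-driven, state-
independent* distribution: module structure concentrates in the leading
principal components of the standardized expression matrix, so each
marker is scored by its best squared correlation with a top-20 PC and
each pair by the best R^2 of its four-cell genotype factor on a top PC
(covering marginal, mixed and purely epistatic pairs); a softmax
(temperature 2 on the Fisher-z scale) of these scores gives the proposal
weights. Proposal densities stay exact, so the chains remain valid; the
weighting only concentrates proposals where the data shows any signal.
Pair proposals are attempted many times per module per sweep (a specific
pair among `C(M, 2)` candidates is otherwise essentially never
proposed).

**Tempering.** `n_chains` chains run at inverse temperatures
`1 = beta_1 > beta_2 > ...`, swapping adjacent states every
`swap_interval` sweeps. The tempered target raises the collapsed
likelihood and indicator prior to `beta` with the expression block
tempered as `log int [p(Y|alpha,mu) p(alpha) p(mu)]^beta` (power the
integrand, not the integral), which keeps every conjugate draw exact at
every temperature; swap acceptance uses the general two-density formula.
One consequence: the `beta -> 0` limit flattens the pure-power marker
terms but not the expression terms (their tempered normalizer depends on
the block dimensions). Default ladder spacing is 0.005; at the data sizes
used here the log-posterior scale is ~10^4, so wider spacing would never
swap.

**Diagnostics.** The cold chain's log posterior is recorded every sweep;
`summarize` reports its autocorrelation. Snapshots are thinned post
burn-in. Identical (data, config, seed) reproduce traces bit-exactly.

## Post-processing

The primary detection score is the label-invariant **pair posterior**
(fraction of snapshots in which a gene and a marker co-occupy a non-null
module). Per-gene module labels for posterior plots are obtained by
greedy maximum-overlap alignment of each snapshot's modules to the final
snapshot. Dense marker maps dilute posteriors across linked markers;
window smoothing sums the posterior over each marker's contiguous
`r^2 > window_r2` window onto the central marker (capped at 1), selects
peaks greedily, and masks the window remainder. Module calls threshold the
aligned gene posterior and smoothed marker posterior at 0.8. The two-locus
interaction test averages the member genes' standardized expression,
computes the residual sum of squares under the additive model (grand mean
plus locus main effects) and under the four-cell-means model, and refers
`F = (SSE_add - SSE_full) / (SSE_full / (N - 4))` to `F(1, N-4)`.

## The simulator

The generator emulates an inbred haploid cross: independent Bernoulli(1/2)
binary markers (optionally a first-order Markov chain for LD studies).
Each module derives from a core gene `mu_{jk}(genotypes) + e` with the
2x2 genotypic-mean table chosen so the two-way ANOVA of `Var(mu)` under
uniform cell frequencies hits a prescribed (locus1, locus2, epistasis)
triple — under uniform haploid frequencies the table is the exact
orthogonal-contrast form `sqrt(L1) s1 + sqrt(L2) s2 + sqrt(Epi) s1 s2`
with `s = +/-1`. The noise `e` is scaled so the genotypic means explain
`h^2 = 0.6` of the core's variance in expectation; each module gene is
`rho * core + sqrt(1 - rho^2) * noise` with `rho = 0.5`, standardized, so
the genotype model explains `h^2 rho^2 = 0.15` of a module gene in
expectation. Presets A-H span balanced (A) to nearly pure epistasis
(B, H) to single-locus dominance (E-G); their triples are normalized to
sum to one before construction (the published triples sum to 0.995-1.014).

What the generator does *not* emulate: LD beyond the optional first-order
Markov chain, non-Gaussian expression noise, dispersed gene-core
correlations (available via `rho_dispersion` but off by default),
batch/array structure, and missing data. Passing benchmarks on these data
therefore demonstrate the machinery, not robustness to real-data
artefacts.

## Problem sizes used by the test suite

The original experiments average 100 replicates of 10^6-iteration chains
with 15-30 tempering ladders. The package's own checks scale this to a
single CPU as a design choice:

- the power comparison keeps the published module design intact — eight
  40-gene two-locus modules, 120 individuals, 640 true gene-marker pairs —
  and reduces only nuisance dimensions (150 instead of 500 markers, 80
  instead of 680 noise genes), 3 replicates, 6000 sweeps, 3 chains;
- the structure-recovery check uses two modules (one single-locus, one
  epistatic) with 200 genes, 100 markers and the original 120 individuals
  (at 60 individuals the weakest module genes are below the information
  needed to reach a 0.8 posterior no matter how long the chain runs);
- exactness checks (enumeration, kernel invariance, oracle integrals) are
  scale-free.

## Known limitations

- `D` is fixed; module birth/death across `D` is not sampled (extraneous
  modules drain to empty instead).
- The published penalty constants and Table 2's numeric cells are not
  recoverable from the source text; the defaults above are this package's
  own null-calibrated choices, and the preset tables are reconstructed
  from the printed variance decompositions.
- Single markers cannot belong to two modules simultaneously; dense-map
  pleiotropy is recovered through the LD window instead (surrogate
  markers), as in the original analysis.
- The Markov-chain LD marker model with forward-summation-backward-
  sampling is deliberately not implemented (reported inferior to the
  exclusion heuristic by the original authors).
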