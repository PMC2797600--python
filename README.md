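# bpeqtl

Bayesian partition modelling of **pleiotropic and epistatic eQTL
modules** in segregating populations (yeast segregant crosses and similar
designs).

## The problem

Expression QTL studies regress thousands of transcript levels on
thousands of marker genotypes one pair at a time. That scheme struggles
exactly where the biology is most interesting: groups of co-regulated
genes responding to a *common* locus set (pleiotropy), and locus pairs
whose effect is interactive with weak marginal signals (epistasis), which
single-marker scans cannot see at all.

`bpeqtl` instead models everything jointly. Genes, markers and
individuals are partitioned into *modules*: a module is a gene set plus a
marker set linked through a latent **individual type** `k`, conditional
on which expression and genotypes are independent. Expression in module
`d` follows the ANOVA model

    y_gi = alpha_g + mu_k(i) + r_i + eps_gi,

while the module's joint marker genotype is multinomial with
type-specific frequencies — so a type can encode any genotype
combination, including purely interactive (XOR-like) patterns. Gene and
type effects, and all multinomial frequencies, are integrated out under
conjugate priors; a Markov chain Monte Carlo sampler (collapsed Gibbs,
Metropolis-Hastings, reversible-jump split-merge over types, joint
marker-and-type moves, parallel tempering) explores the partition space.
Posterior co-membership frequencies of (gene, marker) pairs are the
detection score; modules are called at posterior 0.8.

The package also ships the two-locus epistasis simulator used to
benchmark the method (controlled variance decomposition between locus 1,
locus 2 and epistasis; core-gene heritability 0.6; gene-core correlation
0.5), a two-stage step-wise regression baseline ("SR"), and ROC
evaluation of gene-marker pair detection. On the simulated eight-module
design the partition model detects >500 of 640 true gene-marker pairs at
50 false positives where the regression baseline plateaus near 100-150 —
the gap is largest for modules whose loci interact with little marginal
effect.

## Worked example

```python
import numpy as np
from bpeqtl import BayesianPartitionModel, interaction_test
from bpeqtl.simulate import (ModuleDesign, MultiLocusModel,
                             model_from_decomposition,
                             PRESET_DECOMPOSITIONS, simulate_dataset)

rng = np.random.default_rng(42)
designs = [
    ModuleDesign(MultiLocusModel(np.array([1.0, -1.0])), 60, (10,)),   # one locus
    ModuleDesign(model_from_decomposition(*PRESET_DECOMPOSITIONS["B"]),
                 40, (30, 70)),                                        # epistatic pair
]
expr, geno, truth = simulate_dataset(designs, rng, N=120, M=100, G=200)

model = BayesianPartitionModel(expr, geno, n_modules=4)
res = model.fit(n_iterations=5000, burn_in=2500, n_chains=3, seed=5)
print(res.summary())

labels, probs = res.gene_posteriors()
for d in (1, 2):
    genes = np.where(truth.gene_module == d)[0]
    n_ok = int(((labels[genes] > 0) & (probs[genes] >= 0.8)).sum())
    print(f"true module {d}: {n_ok}/{len(genes)} genes recovered at posterior 0.8")
p = interaction_test(expr, np.where(truth.gene_module == 2)[0], geno, 30, 70)
print(f"two-locus interaction p-value (epistatic module): {p:.2e}")
```

```
Bayesian partition model of eQTL modules
========================================================
genes: 200   markers: 100   individuals: 120
modules (D): 4   chains: 3   iterations: 5000
snapshots: 500   final log posterior: -42030.9
adjacent-swap acceptance: 0.92, 0.94
--------------------------------------------------------
module calls at posterior threshold 0.8:
  module 2: 60 genes, markers [mrk10], K~3.0
true module 1: 60/60 genes recovered at posterior 0.8
true module 2: 40/40 genes recovered at posterior 0.8
two-locus interaction p-value (epistatic module): 5.11e-16
```

Reading the output: both simulated gene modules are recovered in full at
the 0.8 posterior threshold and no background gene is misclassified. The
single-locus module is *called* complete with its true marker (`mrk10`;
`K~3.0` is the posterior mean number of individual types). The epistatic
module's genes are grouped perfectly and the two-locus interaction F-test
on their average expression is overwhelming (p ~ 1e-16) even though
neither locus has a marginal effect — but note its marker pair did not
reach the 0.8 call threshold on this particular chain: marker posteriors
for purely epistatic pairs are the slowest-mixing quantity at desk-scale
run lengths, which is why the benchmark suite averages replicates and
scores pairs along the full ROC curve rather than at one threshold.

The same pipeline is scriptable from the shell:

```bash
bpeqtl simulate --design simI --seed 7 --out sim/
bpeqtl run --expression sim/expression.tsv --genotypes sim/genotypes.tsv \
           --n-modules 12 --seed 1 --out run/
bpeqtl summarize --trace run/ --genotypes sim/genotypes.tsv --out modules.tsv
bpeqtl baseline --expression sim/expression.tsv --genotypes sim/genotypes.tsv
bpeqtl evaluate --scores run/ --truth sim/truth.json --out roc.tsv
```

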