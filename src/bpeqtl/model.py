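"""Model/Results interface to the Bayesian partition sampler.

``BayesianPartitionModel`` holds the data and priors;  ``fit`` runs the
MCMC and returns a ``BayesianPartitionResults`` carrying the sample
trace, posterior summaries, module calls and diagnostics.

Example
-------
>>> from bpeqtl import BayesianPartitionModel, simulate
>>> import numpy as np
>>> rng = np.random.default_rng(0)
>>> expr, geno, truth = simulate.simulate_dataset("simI", rng)
>>> model = BayesianPartitionModel(expr, geno, n_modules=12)
>>> res = model.fit(n_iterations=2000, burn_in=1000, seed=1)
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import summary as _summary
from .data import (
    ExpressionMatrix,
    GenotypeMatrix,
    Hyperparameters,
    validate_dataset,
)
from .sampler import (
    ExclusionSet,
    SampleTrace,
    SamplerConfig,
    autocorrelation,
    build_ld_exclusion,
    run_mcmc,
)


class BayesianPartitionModel:
    """Joint Bayesian partition of expression traits, markers and
    individuals into eQTL modules.

    Parameters
    ----------
    expr, geno
        Aligned expression and genotype matrices (same individuals).
    n_modules
        Number of non-null modules ``D``; pick generously (unused modules
        stay empty).
    exclusion
        Optional LD exclusion set; built from ``ld_r_threshold`` when
        omitted.
    **hyper
        Remaining :class:`Hyperparameters` fields.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        geno: GenotypeMatrix,
        n_modules: int,
        exclusion: Optional[ExclusionSet] = None,
        **hyper,
    ):
        report = validate_dataset(expr, geno)
        self.validation = report
        self.expr = expr
        self.geno = geno
        self.hyperparams = Hyperparameters(D=n_modules, **hyper)
        self.exclusion = exclusion

    @classmethod
    def from_dataframes(cls, expr_df, geno_df, n_modules: int, T: int = 2, **hyper):
        """Build from pandas DataFrames (genes x individuals and markers x
        individuals, identifiers in the index)."""
        expr = ExpressionMatrix(
            expr_df.to_numpy(dtype=float),
            [str(i) for i in expr_df.index],
            [str(c) for c in expr_df.columns],
        )
        geno = GenotypeMatrix(
            geno_df.to_numpy(dtype=int),
            [str(i) for i in geno_df.index],
            T,
        )
        return cls(expr, geno, n_modules, **hyper)

    def fit(
        self,
        n_iterations: int = 4000,
        burn_in: Optional[int] = None,
        thinning: int = 5,
        n_chains: int = 3,
        temperatures=None,
        seed: int = 0,
        ld_r_threshold: float = 0.9,
        swap_interval: int = 10,
        progress=None,
    ) -> "BayesianPartitionResults":
        """Run the sampler and wrap its trace in a results object."""
        if burn_in is None:
            burn_in = n_iterations // 2
        if temperatures is None and n_chains > 1:
            temperatures = [1.0 - 0.005 * k for k in range(n_chains)]
        cfg = SamplerConfig(
            n_iterations=n_iterations,
            burn_in=burn_in,
            thinning=thinning,
            n_chains=n_chains,
            temperatures=temperatures,
            seed=seed,
            ld_r_threshold=ld_r_threshold,
            swap_interval=swap_interval,
        )
        exclusion = self.exclusion
        if exclusion is None:
            exclusion = build_ld_exclusion(self.geno, ld_r_threshold)
        trace = run_mcmc(self.expr, self.geno, self.hyperparams, cfg, exclusion)
        return BayesianPartitionResults(self, trace, cfg)


class BayesianPartitionResults:
    """Posterior summaries of a fitted partition model."""

    def __init__(self, model: BayesianPartitionModel, trace: SampleTrace,
                 config: SamplerConfig):
        self.model = model
        self.trace = trace
        self.config = config
        self._pair_posterior = None

    def pair_posterior(self) -> np.ndarray:
        """Gene x marker co-module posterior probabilities."""
        if self._pair_posterior is None:
            self._pair_posterior = _summary.pair_posterior(self.trace)
        return self._pair_posterior

    def gene_posteriors(self):
        """Modal aligned module label and posterior per gene."""
        return _summary.gene_module_posterior(self.trace)

    def modules(self, threshold: float = 0.8, window_r2: float = 0.8,
                with_interactions: bool = False):
        """Thresholded module calls; optionally attach two-locus
        interaction p-values for modules with exactly two markers."""
        calls = _summary.extract_modules(self.trace, self.model.geno, threshold, window_r2)
        if with_interactions:
            for call in calls:
                if len(call.markers) == 2:
                    try:
                        call.interaction_p = _summary.interaction_test(
                            self.model.expr, call.genes, self.model.geno,
                            call.markers[0], call.markers[1],
                        )
                    except ValueError:
                        call.interaction_p = None
        return calls

    def log_posterior_series(self) -> np.ndarray:
        return self.trace.log_posterior

    def log_posterior_autocorrelation(self, max_lag: int = 50) -> np.ndarray:
        post = self.trace.log_posterior[self.config.burn_in:]
        return autocorrelation(post, max_lag)

    def summary(self, threshold: float = 0.8) -> str:
        """Human-readable fit summary."""
        calls = self.modules(threshold=threshold, with_interactions=True)
        lines = [
            "Bayesian partition model of eQTL modules",
            "=" * 56,
            f"genes: {self.model.expr.n_genes}   markers: {self.model.geno.n_markers}"
            f"   individuals: {self.model.expr.n_individuals}",
            f"modules (D): {self.model.hyperparams.D}   chains: {self.config.n_chains}"
            f"   iterations: {self.config.n_iterations}",
            f"snapshots: {self.trace.n_snapshots}   final log posterior: "
            f"{self.trace.log_posterior[-1]:.1f}",
        ]
        if self.config.n_chains > 1:
            rates = ", ".join(f"{r:.2f}" for r in self.trace.swap_rates())
            lines.append(f"adjacent-swap acceptance: {rates}")
        lines.append("-" * 56)
        lines.append(f"module calls at posterior threshold {threshold}:")
        if not calls:
            lines.append("  (none)")
        for call in calls:
            mk = ", ".join(call.marker_ids or [str(m) for m in call.markers])
            extra = ""
            if call.interaction_p is not None:
                extra = f"  interaction p = {call.interaction_p:.2e}"
            lines.append(
                f"  module {call.module}: {len(call.genes)} genes, markers [{mk}],"
                f" K~{call.k_estimate:.1f}{extra}"
            )
        return "\n".join(lines)

    def plot_log_posterior(self, ax=None):
        """Trace plot of the log posterior (stationarity diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.log_posterior)
        ax.axvline(self.config.burn_in, ls="--", c="grey")
        ax.set_xlabel("iteration")
        ax.set_ylabel("log posterior")
        return ax

    def plot_gene_posterior(self, ax=None):
        """Posterior-probability plot: height = modal-classification
        posterior per gene, colour = module."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels, probs = self.gene_posteriors()
        ax.scatter(np.arange(len(probs)), probs, c=labels, s=8, cmap="tab20")
        ax.set_xlabel("gene index")
        ax.set_ylabel("posterior of modal classification")
        ax.set_ylim(0, 1.05)
        return ax
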