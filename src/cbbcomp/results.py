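"""Fitted-model results: estimates, tests, checks and simulation."""

from __future__ import annotations

import numpy as np

from .inference import learn_hyperpriors as _learn
from .inference import save_posterior, summarize

__all__ = ["CompositionResults"]


class CompositionResults:
    """Posterior results of a :class:`~cbbcomp.model.CompositionModel`.

    Carries the posterior draws with their diagnostics and exposes the
    downstream analyses: coefficient summaries, differential composition
    and variability tests, posterior-predictive intervals/simulation and
    hyperprior learning.
    """

    def __init__(self, model, posterior, outlier_mask=None):
        self.model = model
        self.posterior = posterior
        self.outlier_mask = outlier_mask

    # -- summaries -----------------------------------------------------
    def summarize(self, level=0.95):
        """DataFrame of posterior mean/SD/interval per scalar parameter."""
        return summarize(self.posterior, level)

    def summary(self, level=0.95):
        """Human-readable fit summary."""
        model = self.model
        post = self.posterior
        frame = self.summarize(level)
        lines = [
            "Sum-constrained Beta-binomial composition model"
            if model.constrained else
            "Independent Beta-binomial (unconstrained) model",
            f"groups: {model.G}  samples: {model.S}  "
            f"composition coefficients: {model.C}  "
            f"variability coefficients: {model.V}",
            f"prior: {model.prior}"
            + (" + mixture" if model.mixture else ""),
            f"chains: {post.raw.shape[0]}  draws/chain: {post.raw.shape[1]}"
            f"  divergences: {int(post.divergences.sum())}"
            f"  max R-hat: {max(post.rhat.values()):.3f}",
            "",
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.outlier_mask is not None:
            lines.insert(4, f"outliers excluded: "
                            f"{self.outlier_mask.n_outliers}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<CompositionResults groups={self.model.G} "
                f"samples={self.model.S} draws={self.posterior.n_draws}>")

    # -- hypothesis tests ----------------------------------------------
    def test_composition(self, contrast=None, threshold=0.2,
                         fdr_threshold=0.05, level=0.95):
        from .testing import test_composition
        return test_composition(self.posterior, contrast, threshold,
                                fdr_threshold, level)

    def test_variability(self, contrast=None, threshold=0.2,
                         fdr_threshold=0.05, level=0.95):
        from .testing import test_variability
        return test_variability(self.posterior, contrast, threshold,
                                fdr_threshold, level)

    def result_table(self, threshold=0.2, fdr_threshold=0.05, level=0.95):
        """Combined composition (+ variability, if modelled) table."""
        import pandas as pd
        tabs = [self.test_composition(None, threshold, fdr_threshold, level)]
        if self.model.V > 1:
            tabs.append(self.test_variability(None, threshold,
                                              fdr_threshold, level))
        return pd.concat(tabs, ignore_index=True)

    # -- posterior predictive ------------------------------------------
    def predictive_intervals(self, level=0.95, seed=None):
        from .outliers import predictive_intervals
        return predictive_intervals(self.posterior, level, seed=seed)

    def simulate(self, n_replicates=1, seed=None):
        """Posterior-predictive count tables (one per replicate)."""
        from .simulate import simulate_scbb
        model = self.model
        covs = (model.table.covariates.to_dict("list")
                if not model.table.covariates.empty else None)
        return simulate_scbb(self.posterior, model.design, model.vdesign,
                             model.table.totals, seed=seed,
                             n_replicates=n_replicates, covariates=covs)

    def ppc(self, n_replicates=20, seed=None):
        """Rank-paired observed-vs-simulated slope table per group."""
        from .simulate import ppc_slopes
        sims = self.simulate(n_replicates, seed=seed)
        if n_replicates == 1:
            sims = [sims]
        return ppc_slopes(self.model.table, sims)

    # -- transfer / persistence ----------------------------------------
    def learn_hyperpriors(self):
        return _learn(self.posterior)

    def save(self, directory):
        save_posterior(self.posterior, directory)

    # -- plots ----------------------------------------------------------
    def plot_mean_variability(self, ax=None):
        from .plot import plot_mean_variability
        return plot_mean_variability(self, ax=ax)

    def plot_ppc(self, n_replicates=20, seed=None, ax=None):
        from .plot import plot_ppc
        return plot_ppc(self, n_replicates=n_replicates, seed=seed, ax=ax)
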