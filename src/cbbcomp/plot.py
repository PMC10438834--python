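"""Diagnostic plots (matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_mean_variability", "plot_ppc"]


def plot_mean_variability(results, ax=None):
    """Posterior-mean CLR abundance vs log concentration per group."""
    import matplotlib.pyplot as plt

    model = results.model
    post = results.posterior
    i0 = model.design.intercept_row or 0
    iv0 = model.vdesign.intercept_row or 0
    mu = post.gamma[:, :, i0].mean(axis=0)
    om = post.omega[:, :, iv0].mean(axis=0)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mu, om)
    for g, name in enumerate(model.table.group_ids):
        ax.annotate(name, (mu[g], om[g]), fontsize=7)
    if post.lambda0 is not None:
        xs = np.linspace(mu.min(), mu.max(), 50)
        ax.plot(xs, post.lambda0.mean() + post.lambda1.mean() * xs,
                linestyle="--")
    ax.set_xlabel("CLR abundance (posterior mean)")
    ax.set_ylabel("log concentration (posterior mean)")
    return ax


def plot_ppc(results, n_replicates=20, seed=None, ax=None):
    """Observed proportions per group overlaid on simulated replicates."""
    import matplotlib.pyplot as plt

    model = results.model
    sims = results.simulate(n_replicates, seed=seed)
    if n_replicates == 1:
        sims = [sims]
    obs = model.table.proportions()
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, model.G * 0.5), 4))
    pos = np.arange(model.G)
    sim_stack = [np.concatenate([t.proportions()[g] for t in sims])
                 for g in range(model.G)]
    ax.boxplot(sim_stack, positions=pos, widths=0.6, showfliers=False)
    for g in range(model.G):
        vals = obs[g][~np.isnan(obs[g])]
        ax.scatter(np.full(vals.size, pos[g]), vals, s=12, zorder=3)
    ax.set_xticks(pos)
    ax.set_xticklabels(model.table.group_ids, rotation=90, fontsize=7)
    ax.set_ylabel("proportion")
    return ax
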