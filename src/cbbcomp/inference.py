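"""Posterior sampling, summaries, convergence checks and hyperprior transfer."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .model import Hyperpriors, RegressionState
from .sampler import McmcConfig, sample

__all__ = [
    "ConvergenceError",
    "ConvergenceWarning",
    "PosteriorDraws",
    "fit",
    "summarize",
    "required_draws",
    "learn_hyperpriors",
    "save_posterior",
    "load_posterior_draws",
]


class ConvergenceError(RuntimeError):
    """Raised when the sampler fails its convergence checks."""


class ConvergenceWarning(UserWarning):
    pass


def required_draws(level, tail_support=100):
    """Smallest total draw count supporting the interval tails.

    ``tail_support`` counts draws beyond the two interval quantiles
    combined; each tail must hold at least ``ceil(tail_support / 2)``
    draws.  With the defaults (level 0.95, support 100) this gives 2000
    draws: 50 beyond each of the 2.5% and 97.5% quantiles.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    per_tail = ceil(tail_support / 2)
    return int(ceil(2.0 * per_tail / (1.0 - level) - 1e-9))


@dataclass
class PosteriorDraws:
    """Posterior draws with chain structure and diagnostics.

    ``raw`` holds the packed draws (chains, iters, n_params); the unpacked
    views (``gamma``, ``omega``, hyperparameters) are materialized at
    construction.  ``gamma`` includes the sum-constrained last row.
    """

    raw: np.ndarray
    param_names: list
    model: object
    config: McmcConfig
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    divergences: np.ndarray = None
    accept_rate: np.ndarray = None
    outlier_mask: np.ndarray = None

    def __post_init__(self):
        chains, iters, _ = self.raw.shape
        flat = self.raw.reshape(chains * iters, -1)
        G, C, V = self.model.G, self.model.C, self.model.V
        states = [self.model.unpack(theta) for theta in flat]
        self.gamma = np.stack([s.Gamma for s in states])         # (D, G, C)
        self.omega = np.stack([s.omega for s in states])         # (D, G, V)
        if self.model.prior == "hierarchical":
            self.lambda0 = np.array([s.lambda0 for s in states])
            self.lambda1 = np.array([s.lambda1 for s in states])
            self.phi = np.array([s.phi for s in states])
            if self.model.mixture:
                self.lambda0_low = np.array([s.mixture[1] for s in states])
        else:
            self.lambda0 = self.lambda1 = self.phi = None

    @property
    def n_draws(self):
        return self.raw.shape[0] * self.raw.shape[1]

    @property
    def chain_index(self):
        chains, iters, _ = self.raw.shape
        return np.repeat(np.arange(chains), iters)

    def state(self, i):
        """The i-th draw as a :class:`RegressionState`."""
        chains, iters, _ = self.raw.shape
        return self.model.unpack(self.raw.reshape(chains * iters, -1)[i])

    def mean_state(self):
        """Posterior-mean parameters as a :class:`RegressionState`."""
        theta = self.raw.reshape(self.n_draws, -1).mean(axis=0)
        return self.model.unpack(theta)

    def median_state(self):
        """Per-coordinate posterior-median parameters.

        Robust to a single chain lingering in a metastable mode, which
        would drag the mean state far from the posterior bulk.
        """
        theta = np.median(self.raw.reshape(self.n_draws, -1), axis=0)
        return self.model.unpack(theta)

    def linear_predictors(self):
        """Per-draw (mu, log sigma) arrays of shape (D, G, S)."""
        M = np.einsum("dgc,cs->dgs", self.gamma, self.model.X)
        H = np.einsum("dgv,vs->dgs", self.omega, self.model.Xv)
        return M, H


def _diagnostics(raw, param_names):
    import arviz as az
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(raw[..., :])
        rhat_arr = np.atleast_1d(az.rhat(ds)["x"].values)
        ess_arr = np.atleast_1d(az.ess(ds)["x"].values)
    rhat = dict(zip(param_names, rhat_arr))
    ess = dict(zip(param_names, ess_arr))
    return rhat, ess


def fit(model, config=None, check_convergence=True, retries=1, init=None,
        **kwargs):
    """Fit a :class:`~cbbcomp.model.CompositionModel` by HMC.

    Keyword arguments (``chains``, ``warmup_iters``, ``sampling_iters``,
    ``seed`` ...) override fields of ``config``.  ``init`` may be a
    :class:`~cbbcomp.model.RegressionState` to warm-start the chains (used
    by the outlier-robust refits, which start at the previous step's
    posterior).  When the convergence checks fail, the fit is retried
    (``retries`` times, default one) with tripled warmup, longer
    trajectories and a fresh seed before raising.  Returns a
    :class:`~cbbcomp.results.CompositionResults`.
    """
    from .results import CompositionResults

    if model.table.n_samples < 2:
        raise ValueError("at least 2 samples are required to fit")
    cfg = config if config is not None else McmcConfig()
    if kwargs:
        from dataclasses import replace
        cfg = replace(cfg, **kwargs)

    if init is not None:
        base = model.pack(init)

        def init_fn(rng):
            return base + rng.normal(0.0, cfg.jitter, size=base.shape)
    else:
        def init_fn(rng):
            return model.initial_values(rng, jitter=cfg.jitter)

    out = sample(model.log_prob_and_grad, init_fn, cfg,
                 conditional_update=model.make_conditional_update())
    rhat, ess = _diagnostics(out.draws, model.param_names)
    post = PosteriorDraws(raw=out.draws, param_names=model.param_names,
                          model=model, config=cfg, rhat=rhat, ess=ess,
                          divergences=out.divergences,
                          accept_rate=out.accept_rate)

    div_rate = float(out.divergences.sum()) / cfg.total_draws
    hyper = [n for n in model.param_names
             if n in ("lambda0", "lambda1", "log_phi", "log_delta")]
    bad_hyper = {n: rhat[n] for n in hyper if rhat[n] > 1.2}
    if check_convergence and (div_rate > 0.10 or bad_hyper):
        if retries > 0:
            from dataclasses import replace
            harder = replace(
                cfg, warmup_iters=3 * cfg.warmup_iters,
                max_leapfrog=max(cfg.max_leapfrog, 32),
                seed=int((cfg.seed + 7_654_321) % (2**31)))
            warnings.warn(
                "convergence checks failed (divergence rate "
                f"{div_rate:.0%}, R-hat {bad_hyper}); retrying with "
                "longer warmup", ConvergenceWarning, stacklevel=2)
            return fit(model, harder, check_convergence=check_convergence,
                       retries=retries - 1, init=init)
        if div_rate > 0.10:
            raise ConvergenceError(
                f"{div_rate:.0%} divergent transitions (> 10%); consider "
                "more warmup iterations or a smaller target step size")
        raise ConvergenceError(
            f"R-hat > 1.2 on hyperparameters {bad_hyper}; chains have "
            "not mixed — increase warmup/sampling iterations")
    worst = max(rhat.values())
    if worst > 1.05:
        warnings.warn(f"max R-hat {worst:.3f} > 1.05; treat interval "
                      "summaries with caution", ConvergenceWarning,
                      stacklevel=2)
    return CompositionResults(model=model, posterior=post)


def summarize(post, level=0.95):
    """Posterior mean, SD, central interval and diagnostics per parameter.

    Rows cover the full coefficient matrices (including the derived
    zero-sum row of gamma) and the hyperparameters; R-hat and effective
    sample size are computed on each reported quantity itself.
    """
    if post.n_draws == 0:
        raise ValueError("empty posterior")
    if post.n_draws * (1.0 - level) < 40:
        warnings.warn(
            f"{post.n_draws} draws leave fewer than 20 draws per tail at "
            f"level {level}; interval endpoints are noisy", UserWarning,
            stacklevel=2)
    lo_q, hi_q = (1.0 - level) / 2.0, 1.0 - (1.0 - level) / 2.0
    model = post.model

    names, series = [], []

    def add(name, draws):
        names.append(name)
        series.append(np.asarray(draws, dtype=float))

    for c in range(model.C):
        cname = model.design.row_names[c]
        for g in range(model.G):
            add(f"gamma[{model.table.group_ids[g]},{cname}]",
                post.gamma[:, g, c])
    for v in range(model.V):
        vname = model.vdesign.row_names[v]
        for g in range(model.G):
            add(f"omega[{model.table.group_ids[g]},{vname}]",
                post.omega[:, g, v])
    if post.lambda0 is not None:
        add("lambda0", post.lambda0)
        add("lambda1", post.lambda1)
        add("phi", post.phi)
        if model.mixture:
            add("lambda0_low", post.lambda0_low)

    stacked = np.stack(series, axis=-1)  # (D, P)
    chains, iters, _ = post.raw.shape
    rhat, ess = _diagnostics(stacked.reshape(chains, iters, -1), names)
    rows = []
    for name, draws in zip(names, series):
        rows.append({
            "parameter": name,
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
            f"{100 * lo_q:g}%": float(np.quantile(draws, lo_q)),
            f"{100 * hi_q:g}%": float(np.quantile(draws, hi_q)),
            "rhat": rhat[name],
            "ess": ess[name],
        })
    return pd.DataFrame(rows).set_index("parameter")


def learn_hyperpriors(post, floor=1e-6):
    """Posterior summaries of (lambda0, lambda1, phi) as transferable priors.

    The Normal hyperpriors take the posterior means/SDs of lambda0 and
    lambda1 directly; the Gamma hyperprior for phi is moment-matched to the
    posterior mean m and SD v of phi (shape = m^2/v^2, rate = m/v^2).  The
    three are treated as mutually independent.
    """
    if post.lambda0 is None:
        raise ValueError("hyperpriors can only be learned from a "
                         "hierarchical-prior fit")

    def mean_sd(x):
        m = float(np.mean(x))
        s = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        if s < floor:
            warnings.warn("degenerate posterior: SD floored at "
                          f"{floor}", UserWarning, stacklevel=2)
            s = floor
        return m, s

    l0m, l0s = mean_sd(post.lambda0)
    l1m, l1s = mean_sd(post.lambda1)
    pm, ps = mean_sd(post.phi)
    return Hyperpriors(lambda0_mean=l0m, lambda0_sd=l0s,
                       lambda1_mean=l1m, lambda1_sd=l1s,
                       phi_shape=pm * pm / (ps * ps),
                       phi_rate=pm / (ps * ps),
                       gamma_prior_sd=post.model.hp.gamma_prior_sd)


def save_posterior(post, directory):
    """Persist draws (long CSV) plus a JSON metadata file."""
    import os
    os.makedirs(directory, exist_ok=True)
    chains, iters, P = post.raw.shape
    frame = pd.DataFrame({
        "parameter": np.tile(post.param_names, chains * iters),
        "chain": np.repeat(np.arange(chains), iters * P),
        "iteration": np.tile(np.repeat(np.arange(iters), P), chains),
        "value": post.raw.ravel(),
    })
    frame.to_csv(os.path.join(directory, "draws.csv"), index=False,
                 float_format="%.9g")
    meta = {
        "param_names": post.param_names,
        "chains": chains,
        "sampling_iters": iters,
        "seed": post.config.seed,
        "warmup_iters": post.config.warmup_iters,
        "rhat": {k: float(v) for k, v in post.rhat.items()},
        "ess": {k: float(v) for k, v in post.ess.items()},
        "divergences": [int(d) for d in post.divergences]
        if post.divergences is not None else None,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_posterior_draws(directory):
    """Load the raw draw array and metadata written by save_posterior."""
    import os
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    frame = pd.read_csv(os.path.join(directory, "draws.csv"))
    chains, iters = meta["chains"], meta["sampling_iters"]
    P = len(meta["param_names"])
    raw = frame["value"].to_numpy().reshape(chains, iters, P)
    return raw, meta
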