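"""Adaptive Hamiltonian Monte Carlo.

A self-contained gradient-based MCMC engine behind the single
``sample(logp_grad, init, cfg)`` contract, so that any other gradient-based
backend targeting the same joint density could be swapped in.

Chains run in lockstep with cross-chain warmup adaptation:

* dual-averaging step-size adaptation toward a target acceptance rate
  (0.8), driven by the mean acceptance statistic across chains;
* a diagonal mass matrix re-estimated twice during warmup from the warmup
  draws pooled across chains (between-chain spread exposes weakly curved
  posterior directions — e.g. hyperparameters that the likelihood barely
  constrains — that a single chain would underestimate), shrunk toward a
  small constant for stability;
* a jittered number of leapfrog steps (uniform on max_leapfrog/2 ..
  max_leapfrog) to avoid resonant trajectories.

Transitions whose Hamiltonian error exceeds ``divergence_threshold`` are
counted as divergent and rejected.  All randomness is driven by
``numpy.random.Generator`` streams spawned from a single seed, so runs are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["McmcConfig", "SamplerOutput", "sample"]


@dataclass
class McmcConfig:
    """MCMC run configuration (defaults: 4 chains, 300 warmup, 500 draws)."""

    chains: int = 4
    warmup_iters: int = 300
    sampling_iters: int = 500
    seed: int = 0
    target_tail_draws: int = 100
    target_accept: float = 0.8
    max_leapfrog: int = 24
    jitter: float = 0.2
    divergence_threshold: float = 1000.0

    def __post_init__(self):
        if self.chains < 1 or self.warmup_iters < 1 or self.sampling_iters < 1:
            raise ValueError("chains, warmup_iters and sampling_iters must "
                             "be positive")

    @property
    def total_draws(self):
        return self.chains * self.sampling_iters


@dataclass
class SamplerOutput:
    draws: np.ndarray          # (chains, sampling_iters, n_params)
    accept_rate: np.ndarray    # per chain
    divergences: np.ndarray    # per chain
    step_size: float
    logp: np.ndarray           # (chains, sampling_iters)


def _leapfrog(logp_grad, q, p, grad, eps, n_steps, inv_mass):
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp) or not np.all(np.isfinite(grad)):
            return q, p, -np.inf, grad
        p = p + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return q, p, lp, grad


class _DualAveraging:
    """Nesterov primal-averaged step-size adaptation."""

    def __init__(self, eps0, target):
        self.target = target
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, accept_prob):
        self.count += 1
        frac = 1.0 / (self.count + self.t0)
        self.h_bar = ((1 - frac) * self.h_bar
                      + frac * (self.target - accept_prob))
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def restart(self, eps0):
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.count = 0

    @property
    def adapted(self):
        return float(np.exp(self.log_eps_bar))


def sample(logp_grad, init, cfg, conditional_update=None):
    """Run ``cfg.chains`` HMC chains in lockstep with shared adaptation.

    Parameters
    ----------
    logp_grad : callable theta -> (logp, grad)
    init : callable (rng) -> theta, or array of shape (n_params,)
        Per-chain initial points are drawn (or jittered) independently.
    cfg : McmcConfig
    conditional_update : callable (theta, rng) -> theta, optional
        A target-invariant transition (e.g. an exact conditional draw of
        conjugate hyperparameters) interleaved after every HMC step.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains + 1)
    rngs = [np.random.default_rng(s) for s in seeds[:cfg.chains]]
    step_rng = np.random.default_rng(seeds[-1])

    qs, lps, grads = [], [], []
    for c in range(cfg.chains):
        if callable(init):
            q0 = np.asarray(init(rngs[c]), dtype=float)
        else:
            q0 = np.asarray(init, dtype=float) + rngs[c].normal(
                0.0, cfg.jitter, size=len(init))
        lp0, g0 = logp_grad(q0)
        if not np.isfinite(lp0):
            raise ValueError("non-finite log probability at the initial "
                             f"point of chain {c}")
        qs.append(q0)
        lps.append(lp0)
        grads.append(g0)
    n = qs[0].size

    inv_mass = np.ones(n)
    eps = 0.1 / max(np.sqrt(n), 1.0)
    da = _DualAveraging(eps, cfg.target_accept)

    warm = cfg.warmup_iters
    windows = sorted({int(warm * 0.5), int(warm * 0.75)})
    warm_store = []
    draws = np.empty((cfg.chains, cfg.sampling_iters, n))
    logps = np.empty((cfg.chains, cfg.sampling_iters))
    n_accept = np.zeros(cfg.chains, dtype=int)
    n_div = np.zeros(cfg.chains, dtype=int)
    total = warm + cfg.sampling_iters

    for it in range(total):
        warming = it < warm
        accept_probs = []
        for c in range(cfg.chains):
            rng = rngs[c]
            p0 = rng.normal(size=n) / np.sqrt(inv_mass)
            h0 = -lps[c] + 0.5 * np.sum(inv_mass * p0 * p0)
            n_steps = int(step_rng.integers(
                max(1, cfg.max_leapfrog // 2), cfg.max_leapfrog + 1))
            q_new, p_new, lp_new, g_new = _leapfrog(
                logp_grad, qs[c], p0, grads[c], eps, n_steps, inv_mass)
            if np.isfinite(lp_new):
                h1 = -lp_new + 0.5 * np.sum(inv_mass * p_new * p_new)
                delta_h = h0 - h1
            else:
                delta_h = -np.inf
            accept_prob = min(1.0, np.exp(min(delta_h, 0.0)))
            divergent = (not np.isfinite(delta_h)
                         or -delta_h > cfg.divergence_threshold)
            if divergent:
                accept_prob = 0.0
            accept_probs.append(accept_prob)
            if rng.random() < accept_prob:
                qs[c], lps[c], grads[c] = q_new, lp_new, g_new
                if not warming:
                    n_accept[c] += 1
            if conditional_update is not None:
                qs[c] = conditional_update(qs[c], rng)
                lps[c], grads[c] = logp_grad(qs[c])
            if not warming:
                if divergent:
                    n_div[c] += 1
                draws[c, it - warm] = qs[c]
                logps[c, it - warm] = lps[c]
        if warming:
            eps = da.update(float(np.mean(accept_probs)))
            warm_store.append(np.stack(qs))
            if it + 1 in windows and len(warm_store) >= 10:
                # pooled across chains: between-chain spread reveals wide,
                # weakly-identified directions early.  Memoryless windows:
                # the first update discards the initial transient, later
                # ones use only draws gathered since the previous update.
                recent = np.asarray(warm_store[len(warm_store) // 2:]
                                    if it + 1 == windows[0] else warm_store)
                flat = recent.reshape(-1, n)
                var = flat.var(axis=0)
                m = flat.shape[0]
                inv_mass = (m / (m + 5.0)) * var + (5.0 / (m + 5.0)) * 1e-1
                inv_mass = np.clip(inv_mass, 1e-8, 1e8)
                da.restart(eps)
                warm_store = []
            if it == warm - 1:
                eps = da.adapted
    return SamplerOutput(draws=draws,
                         accept_rate=n_accept / cfg.sampling_iters,
                         divergences=n_div,
                         step_size=float(eps),
                         logp=logps)
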