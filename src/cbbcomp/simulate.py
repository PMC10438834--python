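"""Data generators, posterior-predictive checks and the pAUC benchmark.

Three generating families are provided:

* the sum-constrained Beta-binomial itself (posterior-predictive or from
  explicit parameters) — counts are drawn independently given each sample
  total, so simulated column sums need not equal the input totals;
  proportions for posterior-predictive checks are computed within the
  simulated sample;
* the Dirichlet-multinomial (per sample p ~ Dirichlet(alpha), counts ~
  Multinomial(n, p)) — the single-variability compositional baseline;
* a logit-linear-multinomial used for benchmarking: per-group baseline
  logits, a condition effect of +/- ``slope`` added to the logits of the
  differential groups, counts Multinomial within each sample.  This family
  is *not* the fitted model, which keeps method benchmarks fair.

Every generator is seed-deterministic and returns a ``SimTruth`` record
sufficient to recompute any benchmark number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountTable, build_design
from .model import CompositionModel, RegressionState
from .sampler import McmcConfig

__all__ = [
    "SimTruth",
    "simulate_scbb",
    "simulate_scbb_dataset",
    "simulate_dirichlet_multinomial",
    "fit_dirichlet_multinomial",
    "simulate_logit_linear_multinomial",
    "ppc_slopes",
    "ppc_slope_trend",
    "partial_auc",
    "benchmark_run",
    "mean_variability_scan",
]

# generator defaults: the study conditions of the pAUC benchmark
BENCHMARK_DEFAULTS = dict(n_groups=20, n_samples=20, cells_per_sample=1000,
                          slope=1.5, frac_differential=0.4)
# representative single-cell mean-variability line for parametric simulation
SCBB_DEFAULTS = dict(lambda0=5.0, lambda1=-0.8, phi=0.5)


@dataclass
class SimTruth:
    """Ground truth emitted by the generators."""

    family: str
    seed: int = None
    state: RegressionState = None
    alpha: np.ndarray = None
    differential_mask: np.ndarray = None
    variability_mask: np.ndarray = None
    slope: float = None
    signs: np.ndarray = None
    extras: dict = field(default_factory=dict)


def _labels(prefix, n):
    return [f"{prefix}{i + 1}" for i in range(n)]


def _table_from_counts(counts, covariates=None):
    counts = np.asarray(counts, dtype=np.int64)
    G, S = counts.shape
    table = CountTable(counts=counts, totals=counts.sum(axis=0),
                       group_ids=_labels("G", G),
                       sample_ids=_labels("S", S))
    if covariates is not None:
        cov = pd.DataFrame(covariates,
                           index=pd.Index(table.sample_ids, name="sample"))
        table.covariates = cov
    return table


def _state_probs(state, design, vdesign):
    M = state.Gamma @ design.X
    Mc = M - M.max(axis=0, keepdims=True)
    eM = np.exp(Mc)
    P = eM / eM.sum(axis=0, keepdims=True)
    Sig = np.exp(state.omega @ vdesign.X)
    return P, Sig


def simulate_scbb(source, design, vdesign, totals, seed=None,
                  n_replicates=1, covariates=None):
    """Simulate count tables from the sum-constrained Beta-binomial.

    ``source`` is either an explicit :class:`RegressionState` or a fitted
    posterior (``PosteriorDraws``/``CompositionResults``), in which case
    each replicate uses one random posterior draw (the posterior
    predictive).  Counts are drawn independently per (group, sample) given
    the input totals.  Returns one :class:`CountTable` or a list.
    """
    rng = np.random.default_rng(seed)
    totals = np.asarray(totals, dtype=np.int64)
    post = getattr(source, "posterior", source)
    tables = []
    for _ in range(n_replicates):
        if isinstance(post, RegressionState):
            state = post
        else:
            state = post.state(int(rng.integers(post.n_draws)))
        P, Sig = _state_probs(state, design, vdesign)
        alpha = np.clip(P * Sig, 1e-12, None)
        beta = np.clip((1 - P) * Sig, 1e-12, None)
        p = rng.beta(alpha, beta)
        k = rng.binomial(totals[None, :], p)
        tables.append(_table_from_counts(k, covariates))
    return tables[0] if n_replicates == 1 else tables


def simulate_scbb_dataset(n_groups=8, n_samples=10, cells_per_sample=2000,
                          *, n_conditions=1, effect=1.0,
                          frac_differential=0.0, variability_effect=0.0,
                          frac_differential_variability=0.0, gamma_sd=1.0,
                          lambda0=SCBB_DEFAULTS["lambda0"],
                          lambda1=SCBB_DEFAULTS["lambda1"],
                          phi=SCBB_DEFAULTS["phi"], seed=None):
    """Parametric sum-constrained Beta-binomial dataset with known truth.

    Baseline CLR means are Normal(0, gamma_sd) centered to zero sum; log
    concentrations follow the mean-variability line ``lambda0 + lambda1 *
    mu`` with Normal(0, phi) scatter.  With two conditions, differential
    groups receive a +/- ``effect`` shift (random sign, column re-centered
    to keep the zero-sum constraint) and differential-variability groups a
    ``variability_effect`` shift of their log concentration in condition B.

    Returns ``(CountTable, SimTruth)``; the truth records the realized
    state.
    """
    rng = np.random.default_rng(seed)
    G, S = n_groups, n_samples
    mu0 = rng.normal(0.0, gamma_sd, size=G)
    mu0 -= mu0.mean()
    line_noise = rng.normal(0.0, phi, size=G)  # shared group-level scatter

    covariates = None
    diff_mask = np.zeros(G, dtype=bool)
    var_mask = np.zeros(G, dtype=bool)
    signs = np.zeros(G)
    if n_conditions == 2:
        n_diff = int(round(frac_differential * G))
        diff_mask[rng.choice(G, size=n_diff, replace=False)] = True
        signs[diff_mask] = rng.choice([-1.0, 1.0], size=n_diff)
        delta = signs * effect
        delta -= delta.mean()  # keep the condition column zero-sum
        Gamma = np.column_stack([mu0, delta])
        n_var = int(round(frac_differential_variability * G))
        var_mask[rng.choice(G, size=n_var, replace=False)] = True
        # per-condition concentrations follow the mean-variability line at
        # that condition's abundance, so composition changes do not create
        # spurious adjusted differential variability; the differential-
        # variability groups get an extra shift in condition B
        omega_a = lambda0 + lambda1 * mu0 + line_noise
        omega_b = (lambda0 + lambda1 * (mu0 + delta) + line_noise
                   + np.where(var_mask, variability_effect, 0.0))
        omega = np.column_stack([omega_a, omega_b - omega_a])
        condition = np.array(["A"] * (S // 2) + ["B"] * (S - S // 2))
        covariates = {"condition": condition}
    else:
        Gamma = mu0[:, None]
        omega = (lambda0 + lambda1 * mu0 + line_noise)[:, None]

    state = RegressionState(Gamma=Gamma, omega=omega, lambda0=lambda0,
                            lambda1=lambda1, phi=phi)
    # build a scaffold table so designs can be constructed from covariates
    scaffold = _table_from_counts(np.ones((G, S), dtype=int), covariates)
    formula = "~ 1 + condition" if n_conditions == 2 else "~ 1"
    vformula = "~ 1 + condition" if n_conditions == 2 else "~ 1"
    design = build_design(scaffold, formula)
    vdesign = build_design(scaffold, vformula)
    totals = np.full(S, cells_per_sample, dtype=np.int64)
    table = simulate_scbb(state, design, vdesign, totals, seed=rng,
                          covariates=covariates)
    truth = SimTruth(family="scbb", seed=seed, state=state,
                     differential_mask=diff_mask, variability_mask=var_mask,
                     signs=signs, slope=effect,
                     extras={"formula": formula, "vformula": vformula})
    return table, truth


def simulate_dirichlet_multinomial(alpha, n_samples, cells_per_sample=1000,
                                   seed=None):
    """Per sample p ~ Dirichlet(alpha), counts ~ Multinomial(n, p)."""
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be strictly positive")
    rng = np.random.default_rng(seed)
    totals = np.broadcast_to(np.asarray(cells_per_sample, dtype=np.int64),
                             (n_samples,))
    counts = np.empty((alpha.size, n_samples), dtype=np.int64)
    for s in range(n_samples):
        p = rng.dirichlet(alpha)
        counts[:, s] = rng.multinomial(totals[s], p)
    table = _table_from_counts(counts)
    truth = SimTruth(family="dirichlet_multinomial", seed=seed, alpha=alpha)
    return table, truth


def simulate_logit_linear_multinomial(n_groups=BENCHMARK_DEFAULTS["n_groups"],
                                      n_samples=BENCHMARK_DEFAULTS["n_samples"],
                                      cells_per_sample=BENCHMARK_DEFAULTS["cells_per_sample"],
                                      slope=BENCHMARK_DEFAULTS["slope"],
                                      frac_differential=BENCHMARK_DEFAULTS["frac_differential"],
                                      seed=None):
    """Benchmark generator: condition shifts +/- slope on group logits.

    Baseline logits are Normal(0, 1) zero-centered; exactly
    ``round(frac_differential * G)`` groups are differential, each with a
    random sign; counts are Multinomial(cells_per_sample, softmax(logits))
    per sample, with the second half of samples in condition B.
    """
    if not 0.0 <= frac_differential <= 1.0:
        raise ValueError("frac_differential must be in [0, 1]")
    rng = np.random.default_rng(seed)
    G, S = n_groups, n_samples
    base = rng.normal(0.0, 1.0, size=G)
    base -= base.mean()
    n_diff = int(round(frac_differential * G))
    mask = np.zeros(G, dtype=bool)
    mask[rng.choice(G, size=n_diff, replace=False)] = True
    signs = np.zeros(G)
    signs[mask] = rng.choice([-1.0, 1.0], size=n_diff)
    condition = np.array(["A"] * (S // 2) + ["B"] * (S - S // 2))
    counts = np.empty((G, S), dtype=np.int64)
    for s in range(S):
        logits = base + (slope * signs if condition[s] == "B" else 0.0)
        e = np.exp(logits - logits.max())
        counts[:, s] = rng.multinomial(cells_per_sample, e / e.sum())
    table = _table_from_counts(counts, {"condition": condition})
    truth = SimTruth(family="logit_linear_multinomial", seed=seed,
                     differential_mask=mask, signs=signs, slope=slope)
    return table, truth


def fit_dirichlet_multinomial(table, maxiter=500):
    """Maximum-likelihood Dirichlet-multinomial fit (one alpha vector).

    The compositional baseline with a single precision shared by all
    groups; used as the comparison model in posterior-predictive adequacy
    checks.  Requires a fully observed count table.
    """
    from scipy.optimize import minimize
    from scipy.special import digamma, gammaln

    if table.missing_mask.any():
        raise ValueError("Dirichlet-multinomial fit requires a fully "
                         "observed table")
    K = table.counts.astype(float)
    n = table.totals.astype(float)
    G, S = K.shape
    p0 = np.clip(K.sum(axis=1) / K.sum(), 1e-6, None)

    def nll_grad(log_alpha):
        a = np.exp(log_alpha)
        A = a.sum()
        ll = (np.sum(gammaln(A) - gammaln(n + A))
              + np.sum(gammaln(K + a[:, None]) - gammaln(a)[:, None]))
        d_a = (S * digamma(A) - np.sum(digamma(n + A))
               + np.sum(digamma(K + a[:, None]), axis=1) - S * digamma(a))
        return -ll, -d_a * a

    res = minimize(nll_grad, np.log(p0 * 10.0), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return np.exp(res.x)


def ppc_slopes(observed, simulated):
    """Rank-paired observed-vs-simulated proportion slopes per group.

    Observed and simulated proportions are sorted within each group and
    paired by rank (equal-size vectors pair order statistics directly;
    pooled replicates are reduced to the observed ranks' quantiles), then a
    least-squares line through the pairs is fitted.  A slope of 1 indicates
    matching distributions; groups with constant observed proportions get a
    missing slope.
    """
    sims = simulated if isinstance(simulated, (list, tuple)) else [simulated]
    obs_p = observed.proportions()
    sim_p = [t.proportions() for t in sims]
    rows = []
    S = observed.n_samples
    for g, gname in enumerate(observed.group_ids):
        x = np.sort(obs_p[g][~np.isnan(obs_p[g])])
        y_all = np.concatenate([sp[g][~np.isnan(sp[g])] for sp in sim_p])
        if y_all.size == x.size:
            y = np.sort(y_all)
        else:
            probs = (np.arange(x.size) + 0.5) / x.size
            y = np.quantile(y_all, probs)
        if x.size < 2 or np.ptp(x) < 1e-12:
            slope, intercept = np.nan, np.nan
        else:
            slope, intercept = np.polyfit(x, y, 1)
        rows.append({"group": gname, "slope": slope, "intercept": intercept,
                     "abundance": float(np.mean(x)) if x.size else np.nan})
    return pd.DataFrame(rows)


def ppc_slope_trend(slope_table, abundance=None):
    """Regression of the rank-paired slopes against group abundance.

    A well-calibrated model shows no trend (slope CI covering 0) and
    intercept near 1: variability is neither over- nor under-estimated for
    rare or abundant groups.  ``abundance`` defaults to the log of the
    mean observed proportion from the slope table.
    """
    import statsmodels.api as sm
    tab = slope_table.dropna(subset=["slope"])
    x = (np.log(tab["abundance"].to_numpy())
         if abundance is None else np.asarray(abundance, dtype=float))
    y = tab["slope"].to_numpy()
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int()
    return {"intercept": float(res.params[0]), "slope": float(res.params[1]),
            "slope_ci": (float(ci[1][0]), float(ci[1][1])),
            "pvalue": float(res.pvalues[1])}


def partial_auc(scores, truth, fpr_max=0.1):
    """Unnormalized ROC area for false-positive rates up to ``fpr_max``.

    ``scores`` are ranked descending (larger = called positive first).  A
    perfect ranking yields ``fpr_max``; a random one fpr_max^2 / 2 (0.005
    at the default cap).
    """
    from sklearn.metrics import roc_curve
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(truth.astype(int), scores)
    grid = np.unique(np.concatenate([fpr[fpr <= fpr_max], [fpr_max]]))
    tpr_i = np.interp(grid, fpr, tpr)
    return float(np.trapezoid(tpr_i, grid))


def significance_scores(result_table):
    """Ranking scores from a test table: ascending null probability, ties
    broken by larger absolute effect."""
    p = result_table["prob_null"].to_numpy()
    e = np.abs(result_table["effect_mean"].to_numpy())
    order = np.lexsort((-e, p))  # best first
    scores = np.empty(len(p))
    scores[order] = -np.arange(len(p), dtype=float)
    return scores


def benchmark_run(slopes=(BENCHMARK_DEFAULTS["slope"],),
                  n_samples=(BENCHMARK_DEFAULTS["n_samples"],),
                  n_groups=(BENCHMARK_DEFAULTS["n_groups"],),
                  cells_per_sample=(BENCHMARK_DEFAULTS["cells_per_sample"],),
                  frac_differential=BENCHMARK_DEFAULTS["frac_differential"],
                  replicates=5, seed=0, robust=True, config=None,
                  threshold=0.2, fpr_max=0.1):
    """pAUC benchmark over a grid of simulation settings.

    For every grid cell and replicate: simulate from the logit-linear-
    multinomial generator, fit (robustly by default), rank groups by null
    probability of the condition coefficient, and score the partial AUC
    against the simulation truth.  Returns per-cell mean and SD plus the
    per-replicate values; failed fits are recorded and excluded.
    """
    cfg = config if config is not None else McmcConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    cell_id = 0
    for slope in slopes:
        for S in n_samples:
            for G in n_groups:
                for cells in cells_per_sample:
                    paucs, failures = [], 0
                    for r in range(replicates):
                        sim_seed = np.random.SeedSequence(
                            [seed, cell_id, r])
                        table, truth = simulate_logit_linear_multinomial(
                            G, S, cells, slope, frac_differential,
                            seed=sim_seed)
                        try:
                            pauc = _benchmark_one(table, truth, cfg,
                                                  robust, threshold,
                                                  fpr_max,
                                                  fit_seed=int(
                                                      root.entropy % 2**31)
                                                  + cell_id * 1000 + r)
                            paucs.append(pauc)
                        except Exception as err:  # noqa: BLE001
                            failures += 1
                            warnings.warn(f"benchmark fit failed: {err}",
                                          UserWarning, stacklevel=2)
                    rows.append({
                        "slope": slope, "n_samples": S, "n_groups": G,
                        "cells_per_sample": cells,
                        "frac_differential": frac_differential,
                        "replicates": len(paucs), "failures": failures,
                        "pauc_mean": float(np.mean(paucs)) if paucs else np.nan,
                        "pauc_sd": (float(np.std(paucs, ddof=1))
                                    if len(paucs) > 1 else np.nan),
                        "paucs": paucs,
                    })
                    cell_id += 1
    return pd.DataFrame(rows)


def _benchmark_one(table, truth, cfg, robust, threshold, fpr_max, fit_seed):
    from dataclasses import replace
    model = CompositionModel.from_formula(
        table, "~ 1 + condition", "~ 1")
    run_cfg = replace(cfg, seed=fit_seed % (2**31))
    results = (model.fit_robust(run_cfg) if robust else model.fit(run_cfg))
    tab = results.test_composition("condition[B]", threshold=threshold)
    tab = tab.set_index("group").loc[table.group_ids].reset_index()
    return partial_auc(significance_scores(tab), truth.differential_mask,
                       fpr_max)


def mean_variability_scan(table, design=None, vdesign=None, config=None,
                          mixture=False, refit_hierarchical=False,
                          **kwargs):
    """Estimate the mean-variability association without imposing it.

    Fits the model with flat independent priors on the means and log
    concentrations, reports per-group posterior means and 95% intervals,
    and fits a robust line (Huber M-estimator) of log concentration on the
    CLR mean.  Optionally refits with the hierarchical prior to report the
    interval-width shrinkage ratios, and/or with the two-component mixture
    to report per-group posterior membership of the minority component.
    """
    import statsmodels.api as sm

    cfg = config if config is not None else McmcConfig()
    if kwargs:
        from dataclasses import replace
        cfg = replace(cfg, **kwargs)
    model = CompositionModel(table, design, vdesign, prior="independent")
    res = model.fit(cfg)
    i0 = model.design.intercept_row or 0
    iv0 = model.vdesign.intercept_row or 0
    post = res.posterior
    mu_draws = post.gamma[:, :, i0]
    om_draws = post.omega[:, :, iv0]

    def summar(d):
        return (d.mean(axis=0), np.quantile(d, 0.025, axis=0),
                np.quantile(d, 0.975, axis=0))

    mu_m, mu_lo, mu_hi = summar(mu_draws)
    om_m, om_lo, om_hi = summar(om_draws)
    frame = pd.DataFrame({
        "group": table.group_ids, "mu_mean": mu_m, "mu_lo": mu_lo,
        "mu_hi": mu_hi, "omega_mean": om_m, "omega_lo": om_lo,
        "omega_hi": om_hi,
    })
    rlm = sm.RLM(om_m, sm.add_constant(mu_m),
                 M=sm.robust.norms.HuberT()).fit()
    frame["residual"] = om_m - rlm.fittedvalues
    out = {"table": frame, "line_intercept": float(rlm.params[0]),
           "line_slope": float(rlm.params[1]), "flat_results": res}

    if refit_hierarchical:
        hier = CompositionModel(table, model.design, model.vdesign,
                                prior="hierarchical").fit(cfg)
        h_om = hier.posterior.omega[:, :, iv0]
        _, h_lo, h_hi = summar(h_om)
        flat_width = om_hi - om_lo
        hier_width = h_hi - h_lo
        frame["shrinkage_ratio"] = flat_width / hier_width
        out["hierarchical_results"] = hier
    if mixture:
        mixm = CompositionModel(table, model.design, model.vdesign,
                                prior="hierarchical", mixture=True).fit(cfg)
        mp = mixm.posterior
        from .model import MIXTURE_WEIGHT_HIGH
        from scipy.stats import norm
        mu_h = mp.gamma[:, :, i0]
        m_hi = mp.lambda0[:, None] + mp.lambda1[:, None] * mu_h
        m_lo = mp.lambda0_low[:, None] + mp.lambda1[:, None] * mu_h
        om = mp.omega[:, :, iv0]
        la = (np.log(MIXTURE_WEIGHT_HIGH)
              + norm.logpdf(om, m_hi, mp.phi[:, None]))
        lb = (np.log(1 - MIXTURE_WEIGHT_HIGH)
              + norm.logpdf(om, m_lo, mp.phi[:, None]))
        r_low = 1.0 / (1.0 + np.exp(la - lb))
        frame["p_minority_component"] = r_low.mean(axis=0)
        out["mixture_results"] = mixm
    return out
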