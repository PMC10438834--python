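# Methods

## The model

`cbbcomp` estimates differences in the composition (relative abundance) and
in the variability of cell groups — cell types, clusters, taxa — across
biological conditions, from a table of counts `k[g, s]` (group g, sample s)
with sample totals `n[s]`.

Counts are modelled as sum-constrained independent Beta-binomials.  Writing
the Beta-binomial in its mean/concentration form (mean `pi` in (0,1),
concentration `sigma = alpha + beta > 0`, so `alpha = pi*sigma`,
`beta = (1-pi)*sigma`):

```
k[g, s] ~ BetaBinomial(n[s], pi[g, s], sigma[g, s])
pi[:, s] = softmax(M[:, s]),     M = Gamma X
log sigma[g, s] = (Omega Xv)[g, s]
```

`X` (C x S) is the composition design matrix and `Xv` (V x S) the
variability design; `Gamma` is G x C with **every column constrained to sum
to zero**, so the expected proportions lie on the simplex.  The constraint
is what distinguishes this model from a set of independent Beta-binomials:
it reproduces the weak negative correlations among proportions
(compositionality) that a Dirichlet-multinomial also has, while still
allowing a separate concentration per group — which the
Dirichlet-multinomial cannot.  The zero-sum space is parameterized by G-1
free entries per column, the last row being their negative sum; the inverse
link restricted to this space is the centered log-ratio (CLR).

Concentration is the reciprocal notion of variability; results report
variability effects on the `-omega` (negative log concentration) scale so
that positive effects mean "more variable".

### Mean–variability prior

Across cellular-omics datasets, CLR abundance and log concentration are
(log-)linearly associated.  The model exploits this as an adaptive
shrinkage prior.  With an intercept-only variability design:

```
omega[g] ~ Normal(lambda0 + lambda1 * gamma[g, intercept], phi)
lambda0, lambda1 ~ Normal(0, 5)
phi ~ Gamma(20, 40)            # mean 0.5
gamma[g, c] ~ Normal(0, 5)     # free entries
```

With a factor variability design (differential variability), the prior is
applied per condition: for each distinct condition profile `u` of `Xv`,
`eta[g, u] = omega[g, :] . u` gets mean
`lambda0 + lambda1 * mu[g, u]`, where `mu[g, u]` is the composition linear
predictor at that condition (the design columns of the samples in that
condition, averaged when they differ).  This reduces exactly to the
two-condition model in which each per-condition log concentration is
shrunk toward the line at that condition's abundance.

When the composition design has no intercept, the prior anchor falls back
to the row mean of `Gamma` (design choice; the anchor must be some
per-group location summary).

An optional two-component Gaussian mixture on the intercept accommodates
the bimodal association seen in some single-cell RNA-seq datasets: the
higher-intercept (lower-variability) component has fixed weight 0.9, the
minority component 0.1; slope and SD are shared, and ordering is enforced
by parameterizing `lambda0_low = lambda0_high - exp(d)`.  The component
indicator is marginalized (log-sum-exp), the standard choice for
gradient-based samplers.

### Composite likelihood and simulation

The likelihood multiplies independent Beta-binomial terms whose means are
softmax-tied; the counts of a sample are not jointly multinomial, so the
model is a composite likelihood rather than a joint generative
distribution for a sample's count vector.  Posterior-predictive simulation
follows the same reading: each `k[g, s]` is drawn independently given
`n[s]`, so simulated column sums need not reproduce `n[s]` exactly, and
proportions for predictive checks are computed within the simulated
sample.  Missing (sample, group) pairs are dropped from the likelihood —
an absent row is missingness, an explicit zero is data.

## Inference

Sampling is by adaptive Hamiltonian Monte Carlo over an unconstrained
parameterization (free `Gamma` entries; `log phi`; whitened `omega`).  The
engine is behind a single `sample(logp_grad, init, cfg)` contract so any
gradient-based backend targeting the same density could be swapped in.
Gradients of the joint density are analytic (digamma-based) and verified
against finite differences in the test suite.

Defaults are 4 chains, 300 warmup and 500 sampling iterations per chain —
2000 draws, which leaves 50 draws beyond each of the 2.5%/97.5% quantiles
(the `required_draws` rule: the smallest draw count placing
`ceil(support/2)` draws in each tail, 100 combined by default).

Numerical and adaptation choices that matter:

* **Non-centered omega.**  The hierarchical prior is sampled as
  `z ~ Normal(0, 1)` with `omega` reconstructed as
  `lambda0 + lambda1*mu + phi*z` (per condition unit).  The centered
  parameterization mixes poorly on data with little overdispersion
  (near-multinomial counts), where the likelihood is flat in `omega` above
  a threshold and the hyperparameters ride a wide plateau.
* **Cross-chain warmup adaptation.**  Chains run in lockstep; the diagonal
  mass matrix is re-estimated twice during warmup from warmup draws pooled
  across chains (memoryless windows), and a single dual-averaged step size
  targets a 0.8 mean acceptance rate.  Pooling matters for the same
  plateau directions: a single chain underestimates their scale during a
  short warmup, chains jointly do not.
* **Trajectory jitter.**  The number of leapfrog steps is uniform on
  (max/2, max], max 24 by default.
* **Interleaved conjugate updates.**  After every HMC transition the line
  hyperparameters are resampled exactly: (lambda0, lambda1) from their
  conditional bivariate normal given the concentrations (a conjugate
  Bayesian line fit), phi by slice sampling its one-dimensional
  conditional, plus a level/tilt Metropolis move of the line with the
  whitened coordinates held fixed (so all concentrations shift with it).
  Each move leaves the joint posterior invariant; together they keep the
  hyperparameters mixing even when the data carry no overdispersion and
  the likelihood barely constrains them.
* **Concentration saturation.**  The log-concentration link passes values
  through identically up to 14 (sigma about 1.2e6 — already binomial to
  machine precision at realistic totals) and then approaches an asymptote
  at 18 through a C^1 tanh ramp.  Without it, data with no
  overdispersion reward arbitrarily large sigma by vanishing likelihood
  gains and the chains crawl a long prior-limited ridge instead of
  equilibrating; the cap is far above any identifiable concentration.
* Initialization is data-driven: CLR of pooled proportions for the
  intercept of `Gamma`, method-of-moments concentrations for `omega`, a
  Theil–Sen pre-fit line for (lambda0, lambda1); chains overdisperse the
  line hyperparameters so warmup can measure their scale when the data do
  not pin them.
* All pmf math is in log space via log-Beta/log-Gamma functions; softmax
  uses max-subtraction; numerically absurd states (|log sigma| > 400,
  |mu| > 100) are rejected outright.
* A fit whose convergence checks fail (divergence rate above 10% or
  R-hat above 1.2 on the hyperparameters) is retried once with tripled
  warmup, longer trajectories and a fresh seed before raising.

Convergence: R-hat and effective sample size (via ArviZ) for every scalar
parameter; a warning above R-hat 1.05, an error above 1.2 on the
hyperparameters or when more than 10% of transitions diverge.

## Hypothesis testing

For a contrast `c` of composition coefficients, the per-group effect draws
are `gamma[g, :] . c` on the CLR scale.  The null probability is
one-sided in the direction of the posterior mean:
`P(null) = 1 - P(effect > t)` (or `< -t`), with fold-change threshold
`t = 0.2` by default on the CLR / log-concentration scale.  Contrasts must
be normalized to max |entry| = 1, because rescaling a contrast changes
what the threshold means.  The false-discovery rate is the running mean of
the null probabilities sorted ascending (a cumulative-average local FDR),
and `significant = fdr < 0.05`.

Differential variability is tested on the composition-adjusted quantity

```
(omega[g, 2] - omega[g, 1]) - lambda1 * (mu[g, 2] - mu[g, 1])
```

computed per posterior draw: because log concentration tracks abundance
through the hierarchical line, the raw difference in concentration would
partly restate the difference in composition; subtracting
`lambda1 * delta-mu` removes that leakage, making variability calls
informative beyond composition calls.  Matching of variability to
composition contrasts is by coefficient name across the two designs.

## Outlier detection

Three steps, two flagging iterations (enough in practice):

1. Fit on all data; flag observations outside the central 95% interval of
   the *fitted* Beta-binomial (simulated at the posterior-median state, with
   at least `required_draws(level)` replicates per observation).  By
   construction roughly 5% of clean observations fall outside (measured
   ~2.5–3% on simulated data: the fitted parameters adapt somewhat to the
   points being tested).  We deliberately use fitted-state intervals here
   rather than the full posterior-predictive mixture: the mixture's extra
   parameter-uncertainty width makes in-sample flagging severely
   under-fire at realistic sample sizes (~1.4% instead of ~5% at 10
   samples).  The mixture intervals remain available
   (`predictive_intervals(..., mode="mixture")`) and are what the
   posterior-predictive check uses.
2. Refit without the flagged observations.  Removal cuts the tails of the
   retained data, which biases variance estimates downward, so retained
   observations in any group that lost a point use a *truncated*
   Beta-binomial conditioned on that cell's step-1 interval (censoring
   adjustment).  Re-flag with stricter per-observation intervals of
   two-sided tail mass `0.05/S`, moving the expected false-positive unit
   from observation pairs to groups (about 5% of groups).
3. Fit once more excluding the final mask and compute the tests.  When the
   final mask is empty the step-1 fit is reused unchanged.

The refits of steps 2 and 3 warm-start their chains at the previous
step's posterior median state: the refit posterior bulk is nearby, and
starting there keeps chains out of the degenerate basins the truncated
likelihood admits for sparse group-condition cells (a near-zero fitted
mean makes the window-conditional likelihood almost flat).  The flagging
intervals likewise use the posterior median state, which is robust to a
single chain lingering in such a basin.

The truncation normalizer and its gradient are evaluated jointly over all
truncated cells on a padded support-window matrix, using the pmf
successive-ratio recurrence and the digamma recurrence
`psi(x+1) = psi(x) + 1/x` along each window, with special functions only
at window edges.

## Simulation and benchmarking

Three generating families, all seed-deterministic and returning the ground
truth needed to recompute any benchmark number:

* **Sum-constrained Beta-binomial** — from an explicit parameter state or
  from a fitted posterior (posterior predictive).  The parametric
  generator's default mean–variability line is `lambda0 = 5.0`,
  `lambda1 = -0.8`, `phi = 0.5` with baseline CLR means Normal(0, 1) —
  concentrations of roughly 30–400 at typical abundances, representative
  of single-cell RNA-seq cell-type counts.
* **Dirichlet-multinomial** — `p ~ Dirichlet(alpha)` per sample, counts
  multinomial; the single-variability compositional baseline.  The
  four-group fixture `alpha = (0.2, 0.6, 2.0, 4.0)` exercises rare-group
  compositional correlation.
* **Logit-linear-multinomial** — benchmark generator, deliberately *not*
  the fitted model: baseline logits Normal(0, 1) zero-centered, a
  condition shift of +/- slope (random sign per group) on a configured
  fraction of groups, multinomial counts.  Benchmark defaults are the
  large-effect design: slope 1.5, 20 samples (10 per condition), 20
  groups, 1000 cells per sample, 40% of groups differential.

The posterior-predictive check sorts observed and simulated proportions
within each group, pairs them by rank, and fits a least-squares line; a
slope of 1 per group indicates distributional match, and the regression
of slopes on group abundance (no trend, intercept 1) checks that
variability is neither over- nor under-estimated for rare or abundant
groups.  Benchmarks score methods by the unnormalized ROC area up to a
false-positive rate of 0.1 (maximum 0.1; 0.005 for random ranking),
ranking groups by ascending null probability with ties broken by absolute
effect.

`mean_variability_scan` estimates the association without imposing it
(flat independent priors), fits a robust line (Huber M-estimator) through
the per-group posterior means, and optionally reports the interval
shrinkage obtained by turning the hierarchical prior on, or per-group
posterior membership of the minority mixture component.

## Cross-dataset transfer

`learn_hyperpriors` turns a fitted posterior into an informative
`Hyperpriors` record: posterior means/SDs of `lambda0` and `lambda1`
directly, and a moment-matched Gamma for `phi`
(`shape = m^2/sd^2`, `rate = m/sd^2`), treated as mutually independent.
Fitting a new (small) dataset with such a record regularizes its
mean–variability line.

## Problem sizes and what the tests show

The test suite and the acceptance script run everything at desk scale,
chosen to leave clear statistical margins: outlier calibration uses ten
8-group x 10-sample x 2000-cell datasets; the benchmark uses five
replicates of the large-effect design; recovery uses twenty 5-group
fits; end-to-end suite runs use 2 chains (the acceptance script uses the
default 4).  The generators emulate overdispersed compositional counts
with a log-linear mean–variability association and, in the benchmark, a
model-mismatched multinomial noise floor.  They do not emulate batch
effects, clustering/annotation error upstream of counting, doublets, or
covariate-dependent missingness — passing tests say the estimator and its
calibration work under the model family and fair off-model noise, not
that real datasets meet those assumptions.

## Known limitations

* The multi-category (ANOVA-like) omnibus factor test via leave-one-out
  cross-validation is out of scope; test contrasts one at a time.
* Variability non-centering requires the condition profiles of the
  variability design to form an invertible map (intercept-only and factor
  designs qualify); other designs fall back to the centered
  parameterization and may need longer warmup.
* On data with essentially no overdispersion the concentrations are only
  bounded below, and their posteriors (and `lambda0`) are prior-limited;
  composition inference is unaffected.
* Per-cell metadata ingestion expects a plain table; single-cell
  container objects (AnnData/Seurat/SingleCellExperiment) are not parsed.
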