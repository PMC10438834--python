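"""Joint log density, analytic gradients and model invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cbbcomp as cb
from cbbcomp.model import (CompositionModel, Hyperpriors, RegressionState,
                           adjusted_diff_variability, joint_log_prob)


def _random_table(seed=0, G=5, S=6, with_condition=True):
    rng = np.random.default_rng(seed)
    counts = rng.integers(5, 300, size=(G, S))
    table = cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                          group_ids=[f"G{i}" for i in range(G)],
                          sample_ids=[f"S{i}" for i in range(S)])
    if with_condition:
        table.covariates = pd.DataFrame(
            {"condition": ["A"] * (S // 2) + ["B"] * (S - S // 2)},
            index=pd.Index(table.sample_ids, name="sample"))
    return table


def _fd_gradient(model, theta, eps=1e-5):
    num = np.empty_like(theta)
    for i in range(theta.size):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += eps
        tm[i] -= eps
        num[i] = (model.log_prob(tp) - model.log_prob(tm)) / (2 * eps)
    return num


class TestGradients:
    @pytest.mark.parametrize("kwargs", [
        {},                                           # non-centered hierarchical
        {"mixture": True},                            # centered mixture
        {"prior": "independent"},
        {"constrained": False, "prior": "independent"},
    ], ids=["hierarchical", "mixture", "independent", "unconstrained"])
    def test_matches_finite_differences(self, kwargs):
        table = _random_table()
        model = CompositionModel.from_formula(
            table, "~ 1 + condition", "~ 1 + condition", **kwargs)
        theta = model.initial_values(np.random.default_rng(1))
        _, grad = model.log_prob_and_grad(theta)
        num = _fd_gradient(model, theta)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-4)

    def test_log_prob_only_matches_gradient_path(self):
        table = _random_table(seed=4)
        K = table.counts
        trunc = {(1, 1): (max(0, K[1, 1] - 20), K[1, 1] + 25)}
        for kwargs in ({}, {"mixture": True}, {"prior": "independent"}):
            model = CompositionModel(table, truncation=trunc, **kwargs)
            theta = model.initial_values(np.random.default_rng(2))
            assert model.log_prob_only(theta) == pytest.approx(
                model.log_prob(theta), abs=1e-9)

    def test_gradient_across_concentration_cap(self):
        # eta values straddling the saturation ramp of the sigma link
        table = _random_table(seed=6, with_condition=False)
        model = CompositionModel(table)
        theta = model.initial_values(np.random.default_rng(3), jitter=0.0)
        phi = np.exp(theta[model._i_logphi])
        theta[model._sl_omega] = (np.array([2.0, 6.0, 13.0, 15.5, 22.0])
                                  - theta[model._i_lam0]) / phi
        _, grad = model.log_prob_and_grad(theta)
        # wider step: at saturated sigma the log density is a difference of
        # huge log-gamma values, so small-step differences are noise-bound
        num = _fd_gradient(model, theta, eps=1e-3)
        np.testing.assert_allclose(grad, num, rtol=1e-3, atol=1e-3)

    def test_initial_values_deterministic_without_jitter(self):
        table = _random_table(seed=5)
        model = CompositionModel(table)
        t1 = model.initial_values(np.random.default_rng(0), jitter=0.0)
        t2 = model.initial_values(np.random.default_rng(99), jitter=0.0)
        np.testing.assert_array_equal(t1, t2)

    def test_truncated_likelihood_gradient(self):
        table = _random_table(seed=3, with_condition=False)
        K = table.counts
        trunc = {(0, 0): (max(0, K[0, 0] - 25), K[0, 0] + 30),
                 (2, 3): (0, K[2, 3] + 12),
                 (4, 1): (K[4, 1] - 4, K[4, 1] + 4)}
        model = CompositionModel(table, truncation=trunc)
        theta = model.initial_values(np.random.default_rng(2))
        _, grad = model.log_prob_and_grad(theta)
        num = _fd_gradient(model, theta)
        np.testing.assert_allclose(grad, num, rtol=1e-3, atol=1e-3)


def _oracle_joint(table, design, vdesign, state, hp):
    """Term-by-term reimplementation of the joint density via scipy.stats."""
    M = state.Gamma @ design.X
    P = np.exp(M) / np.exp(M).sum(axis=0, keepdims=True)
    Sig = np.exp(state.omega @ vdesign.X)
    lp = 0.0
    for g in range(table.n_groups):
        for s in range(table.n_samples):
            if table.missing_mask[g, s]:
                continue
            a = P[g, s] * Sig[g, s]
            b = (1 - P[g, s]) * Sig[g, s]
            lp += stats.betabinom.logpmf(table.counts[g, s],
                                         table.totals[s], a, b)
    i0 = design.intercept_row
    for g in range(table.n_groups):
        m = state.lambda0 + state.lambda1 * state.Gamma[g, i0]
        lp += stats.norm.logpdf(state.omega[g, 0], m, state.phi)
    lp += stats.norm.logpdf(state.Gamma[:-1, :], 0, hp.gamma_prior_sd).sum()
    lp += stats.norm.logpdf(state.lambda0, hp.lambda0_mean, hp.lambda0_sd)
    lp += stats.norm.logpdf(state.lambda1, hp.lambda1_mean, hp.lambda1_sd)
    lp += stats.gamma.logpdf(state.phi, hp.phi_shape, scale=1 / hp.phi_rate)
    return float(lp)


class TestJointLogProb:
    def test_matches_term_by_term_oracle(self):
        table = _random_table(seed=5, with_condition=True)
        design = cb.build_design(table, "~ 1 + condition")
        vdesign = cb.build_design(table, "~ 1")
        rng = np.random.default_rng(8)
        G = table.n_groups
        gfree = rng.normal(0, 1, size=(G - 1, 2))
        Gamma = np.vstack([gfree, -gfree.sum(axis=0)])
        state = RegressionState(Gamma=Gamma,
                                omega=rng.normal(4, 1, size=(G, 1)),
                                lambda0=4.0, lambda1=-0.5, phi=0.6)
        hp = Hyperpriors()
        ours = joint_log_prob(table, design, vdesign, state, hp)
        oracle = _oracle_joint(table, design, vdesign, state, hp)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_zero_linear_predictor_likelihood(self):
        # Gamma = 0, omega = 0: every pi is 1/2 and sigma is 1
        counts = np.array([[7], [13]])
        table = cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                              group_ids=["a", "b"], sample_ids=["s"])
        design = cb.build_design(table, "~ 1")
        state0 = RegressionState(Gamma=np.zeros((2, 1)),
                                 omega=np.zeros((2, 1)),
                                 lambda0=0.0, lambda1=0.0, phi=0.5)
        lp = joint_log_prob(table, design, design, state0)
        lik = sum(float(cb.betabinom_logpmf(k, 20, 0.5, 1.0))
                  for k in (7, 13))
        prior = (2 * stats.norm.logpdf(0.0, 0.0, 0.5)       # omega | line
                 + stats.norm.logpdf(0.0, 0, 5)             # free gamma row
                 + 2 * stats.norm.logpdf(0.0, 0, 5)         # lambda0/1
                 + stats.gamma.logpdf(0.5, 20, scale=1 / 40))
        assert lp == pytest.approx(lik + prior, abs=1e-8)

    def test_single_group_rejected(self):
        counts = np.array([[10, 20]])
        table = cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                              group_ids=["only"], sample_ids=["s1", "s2"])
        with pytest.raises(ValueError, match="G >= 2"):
            CompositionModel(table)

    def test_tail_count_decreases_density(self):
        table = _random_table(seed=9, with_condition=False)
        design = cb.build_design(table, "~ 1")
        model = CompositionModel(table)
        state = model.unpack(model.initial_values(np.random.default_rng(0),
                                                  jitter=0.0))
        base = joint_log_prob(table, design, design, state)
        counts = table.counts.copy()
        counts[0, 0] = table.totals[0]  # push one count to the extreme tail
        bumped = cb.CountTable(counts=counts, totals=table.totals,
                               group_ids=table.group_ids,
                               sample_ids=table.sample_ids)
        assert joint_log_prob(bumped, design, design, state) < base


class TestParameterization:
    def test_unpacked_gamma_columns_sum_to_zero(self):
        table = _random_table(seed=1)
        model = CompositionModel.from_formula(table, "~ 1 + condition")
        theta = np.random.default_rng(0).normal(size=model.n_params)
        state = model.unpack(theta)
        np.testing.assert_allclose(state.Gamma.sum(axis=0), 0.0, atol=1e-9)

    def test_pack_unpack_round_trip(self):
        table = _random_table(seed=2)
        model = CompositionModel(table)
        theta = np.random.default_rng(3).normal(size=model.n_params)
        state = model.unpack(theta)
        np.testing.assert_allclose(model.pack(state), theta, atol=1e-10)

    def test_mixture_components_ordered(self):
        table = _random_table(seed=4)
        model = CompositionModel(table, mixture=True)
        theta = np.random.default_rng(5).normal(size=model.n_params)
        state = model.unpack(theta)
        hi, lo = state.mixture
        assert hi > lo

    def test_degrees_of_freedom_accounting(self):
        # G-1 free mean parameters per covariate plus the (lambda0,
        # lambda1, phi) variability block: compositional data with G groups
        # needs no more than G+1 effective degrees of freedom
        table = _random_table(seed=6, with_condition=False)
        model = CompositionModel(table)
        G = table.n_groups
        n_gamma = sum(1 for n in model.param_names if n.startswith("gamma["))
        assert n_gamma == G - 1
        assert {"lambda0", "lambda1", "log_phi"} <= set(model.param_names)

    def test_group_losing_all_observations_rejected(self):
        table = _random_table(seed=7, with_condition=False)
        exclude = np.zeros(table.counts.shape, dtype=bool)
        exclude[2, :] = True
        with pytest.raises(ValueError, match="G2"):
            CompositionModel(table, exclude=exclude)


class TestAdjustedDiffVariability:
    def test_zero_slope_gives_raw_difference(self):
        assert adjusted_diff_variability(1.0, 0.4, 2.0, 5.0, 0.0) == \
            pytest.approx(-0.6)

    def test_arithmetic_cancellation(self):
        assert adjusted_diff_variability(0.3, 0.0, 0.0, 0.3, -1.0) == \
            pytest.approx(0.0)

    def test_equal_means_ignore_slope(self):
        for lam1 in (-2.0, 0.0, 3.5):
            assert adjusted_diff_variability(0.2, 0.9, 1.1, 1.1, lam1) == \
                pytest.approx(0.7)

    def test_vectorized_over_draws(self):
        om1 = np.array([0.0, 1.0])
        om2 = np.array([1.0, 1.0])
        out = adjusted_diff_variability(om1, om2, 0.0, 1.0, 0.5)
        np.testing.assert_allclose(out, [0.5, -0.5])
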