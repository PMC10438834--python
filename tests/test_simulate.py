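"""Generators, posterior-predictive slope checks and partial AUC."""

import numpy as np
import pytest

import cbbcomp as cb
from cbbcomp.simulate import (partial_auc, ppc_slopes, significance_scores,
                              simulate_dirichlet_multinomial,
                              simulate_logit_linear_multinomial,
                              simulate_scbb, simulate_scbb_dataset)


class TestDirichletMultinomial:
    def test_mean_proportions_match_analytic(self):
        alpha = np.array([0.2, 0.6, 2.0, 4.0])
        table, truth = simulate_dirichlet_multinomial(
            alpha, n_samples=2000, cells_per_sample=500, seed=0)
        expected = alpha / alpha.sum()
        observed = table.proportions().mean(axis=1)
        np.testing.assert_allclose(observed, expected, atol=0.02)

    def test_large_equal_alpha_concentrates(self):
        table, _ = simulate_dirichlet_multinomial(
            np.full(5, 500.0), n_samples=200, cells_per_sample=2000, seed=1)
        props = table.proportions()
        assert np.abs(props - 0.2).max() < 0.1

    def test_zero_cells_gives_zero_counts(self):
        table, _ = simulate_dirichlet_multinomial(
            [1.0, 1.0], n_samples=1, cells_per_sample=0, seed=2)
        assert table.counts.sum() == 0

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            simulate_dirichlet_multinomial([0.0, 1.0], n_samples=3)


class TestLogitLinearMultinomial:
    def test_benchmark_design_marks_8_of_20(self):
        table, truth = simulate_logit_linear_multinomial(
            n_groups=20, n_samples=20, cells_per_sample=1000, slope=1.5,
            frac_differential=0.4, seed=0)
        assert truth.differential_mask.sum() == 8
        assert table.counts.shape == (20, 20)
        np.testing.assert_array_equal(table.totals, np.full(20, 1000))
        assert list(table.covariates["condition"]) == ["A"] * 10 + ["B"] * 10

    def test_null_slope_conditions_identical_in_distribution(self):
        table, truth = simulate_logit_linear_multinomial(
            n_groups=10, n_samples=400, cells_per_sample=500, slope=0.0,
            frac_differential=0.4, seed=3)
        assert truth.differential_mask.sum() == 4
        pa = table.proportions()[:, :200].mean(axis=1)
        pb = table.proportions()[:, 200:].mean(axis=1)
        np.testing.assert_allclose(pa, pb, atol=0.01)

    def test_seed_determinism_byte_identical(self):
        t1, _ = simulate_logit_linear_multinomial(seed=5)
        t2, _ = simulate_logit_linear_multinomial(seed=5)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_logit_linear_multinomial(frac_differential=1.5)


class TestScbbGenerator:
    def test_binomial_limit_group_means(self):
        # huge concentration: Beta-binomial collapses onto Binomial(n, pi)
        S = 200
        state = cb.RegressionState(Gamma=np.zeros((2, 1)),
                                   omega=np.full((2, 1), 15.0))
        scaffold = cb.CountTable(counts=np.ones((2, S), dtype=int),
                                 totals=np.full(S, 2),
                                 group_ids=["a", "b"],
                                 sample_ids=[f"s{i}" for i in range(S)])
        design = cb.build_design(scaffold, "~ 1")
        sims = simulate_scbb(state, design, design,
                             totals=np.full(S, 1000), seed=0)
        sd = np.sqrt(1000 * 0.25)
        assert abs(sims.counts[0].mean() - 500) < 3 * sd / np.sqrt(S)

    def test_marginal_means_match_softmax(self):
        table, truth = simulate_scbb_dataset(n_groups=6, n_samples=300,
                                             cells_per_sample=2000, seed=9)
        M = truth.state.Gamma[:, 0]
        expected = np.exp(M) / np.exp(M).sum()
        observed = table.proportions().mean(axis=1)
        np.testing.assert_allclose(observed, expected, atol=0.02)

    def test_seed_determinism(self):
        t1, _ = simulate_scbb_dataset(seed=4)
        t2, _ = simulate_scbb_dataset(seed=4)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_two_condition_truth_masks(self):
        table, truth = simulate_scbb_dataset(
            n_groups=10, n_samples=12, n_conditions=2, effect=1.0,
            frac_differential=0.3, seed=5)
        assert truth.differential_mask.sum() == 3
        # condition column of the true Gamma stays zero-sum
        assert truth.state.Gamma[:, 1].sum() == pytest.approx(0.0, abs=1e-12)


class TestPpcSlopes:
    def test_identity_gives_exact_unit_slopes(self, small_table):
        tab = ppc_slopes(small_table, small_table)
        np.testing.assert_allclose(tab["slope"], 1.0, atol=1e-12)

    def test_doubled_proportions_give_slope_two(self):
        # build a table whose proportions are exactly twice the observed
        # ones (all observed proportions < 0.5, so no clipping needed)
        rng = np.random.default_rng(0)
        counts = rng.integers(80, 120, size=(3, 10))
        obs = cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                            group_ids=["a", "b", "c"],
                            sample_ids=[f"s{i}" for i in range(10)])
        doubled = counts.astype(float) / counts.sum(axis=0) * 2
        sim = cb.CountTable(counts=np.round(doubled * 10000).astype(int),
                            totals=np.full(10, 10000),
                            group_ids=obs.group_ids,
                            sample_ids=obs.sample_ids)
        tab = ppc_slopes(obs, sim)
        np.testing.assert_allclose(tab["slope"], 2.0, atol=0.01)

    def test_constant_proportions_reported_missing(self):
        counts = np.array([[10, 10, 10], [30, 30, 30]])
        obs = cb.CountTable(counts=counts, totals=counts.sum(axis=0),
                            group_ids=["a", "b"],
                            sample_ids=["s1", "s2", "s3"])
        tab = ppc_slopes(obs, obs)
        assert tab["slope"].isna().all()

    def test_pooled_replicates_supported(self, small_table):
        tab = ppc_slopes(small_table, [small_table, small_table])
        assert len(tab) == small_table.n_groups
        np.testing.assert_allclose(tab["slope"].dropna(), 1.0, atol=0.35)


class TestDirichletMultinomialFit:
    def test_mle_recovers_generating_alpha(self):
        alpha = np.array([0.5, 1.5, 4.0, 8.0])
        table, _ = simulate_dirichlet_multinomial(
            alpha, n_samples=400, cells_per_sample=800, seed=11)
        est = cb.fit_dirichlet_multinomial(table)
        np.testing.assert_allclose(est, alpha, rtol=0.25)

    def test_missing_cells_rejected(self, small_table):
        import copy
        t = copy.deepcopy(small_table)
        t.missing_mask[0, 0] = True
        with pytest.raises(ValueError, match="fully"):
            cb.fit_dirichlet_multinomial(t)


class TestPpcSlopeTrend:
    def test_flat_slopes_cover_zero(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"slope": 1 + 0.05 * rng.normal(size=30),
                            "abundance": np.geomspace(0.01, 0.4, 30),
                            "group": range(30)})
        trend = cb.ppc_slope_trend(tab)
        lo, hi = trend["slope_ci"]
        assert lo <= 0 <= hi
        assert abs(trend["intercept"] - 1) < 0.2

    def test_abundance_trend_detected(self):
        import pandas as pd
        abundance = np.geomspace(0.01, 0.4, 30)
        tab = pd.DataFrame({"slope": 1 - 0.3 * np.log(abundance),
                            "abundance": abundance, "group": range(30)})
        trend = cb.ppc_slope_trend(tab)
        assert trend["pvalue"] < 1e-6 and trend["slope"] < 0


class TestBenchmarkRun:
    def test_single_cell_grid_row(self):
        frame = cb.benchmark_run(
            slopes=(2.0,), n_samples=(10,), n_groups=(8,),
            cells_per_sample=(400,), frac_differential=0.5, replicates=1,
            seed=5, robust=False,
            config=cb.McmcConfig(chains=2, warmup_iters=150,
                                 sampling_iters=200))
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row["replicates"] == 1 and row["failures"] == 0
        assert 0.0 <= row["pauc_mean"] <= 0.1


class TestPartialAuc:
    def test_perfect_separation_reaches_cap(self):
        truth = np.array([True] * 5 + [False] * 15)
        scores = -np.arange(20, dtype=float)
        assert partial_auc(scores, truth, 0.1) == pytest.approx(0.1)

    def test_random_scores_near_analytic_floor(self):
        rng = np.random.default_rng(1)
        truth = rng.random(20000) < 0.4
        scores = rng.normal(size=20000)
        assert partial_auc(scores, truth, 0.1) == pytest.approx(0.005,
                                                                abs=0.002)

    def test_constant_scores_exactly_floor(self):
        truth = np.array([True, False] * 10)
        assert partial_auc(np.zeros(20), truth, 0.1) == pytest.approx(0.005)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            partial_auc(np.arange(4.0), np.ones(4, dtype=bool))

    def test_significance_scores_rank_by_prob_then_effect(self):
        import pandas as pd
        tab = pd.DataFrame({"prob_null": [0.5, 0.0, 0.0, 0.9],
                            "effect_mean": [1.0, 0.3, -2.0, 0.1]})
        s = significance_scores(tab)
        assert np.argmax(s) == 2       # prob 0 with the largest |effect|
        assert np.argmin(s) == 3       # prob 0.9
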