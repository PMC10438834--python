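"""Model behavior on simulated data: calibration, recovery, adjustment.

These tests run real (small) MCMC fits; sizes are chosen so each fit takes
a few seconds while leaving clear statistical margins.
"""

import numpy as np
import pytest
from scipy import stats

import cbbcomp as cb
from cbbcomp.simulate import mean_variability_scan
from tests.conftest import FAST_CFG


class TestNullCalibration:
    def test_no_effects_few_discoveries(self):
        table, truth = cb.simulate_scbb_dataset(
            n_groups=10, n_samples=20, cells_per_sample=1500,
            n_conditions=2, effect=0.0, frac_differential=0.0, seed=21)
        model = cb.CompositionModel.from_formula(table, "~ 1 + condition")
        res = model.fit(cb.McmcConfig(seed=22, **FAST_CFG))
        tab = res.test_composition("condition[B]")
        # all groups are null: at most 10% may be called significant
        assert tab["significant"].mean() <= 0.10

    def test_null_effects_center_on_zero(self):
        table, _ = cb.simulate_scbb_dataset(
            n_groups=10, n_samples=20, cells_per_sample=1500,
            n_conditions=2, effect=0.0, frac_differential=0.0, seed=23)
        model = cb.CompositionModel.from_formula(table, "~ 1 + condition")
        res = model.fit(cb.McmcConfig(seed=24, **FAST_CFG))
        tab = res.test_composition("condition[B]")
        assert np.abs(tab["effect_mean"]).max() < 0.5


class TestDifferentialVariability:
    @pytest.fixture(scope="class")
    def dv_fit(self):
        table, truth = cb.simulate_scbb_dataset(
            n_groups=12, n_samples=20, cells_per_sample=2000,
            n_conditions=2, effect=0.8, frac_differential=0.25,
            variability_effect=-1.5, frac_differential_variability=0.25,
            seed=33)
        model = cb.CompositionModel.from_formula(
            table, "~ 1 + condition", "~ 1 + condition")
        res = model.fit(cb.McmcConfig(seed=34, **FAST_CFG))
        return res, truth

    def test_differentially_variable_groups_rank_first(self, dv_fit):
        res, truth = dv_fit
        tab = res.test_variability("condition[B]").set_index("group")
        order = tab.sort_values("prob_null").index
        var_groups = {f"G{i + 1}" for i in
                      np.flatnonzero(truth.variability_mask)}
        k = len(var_groups)
        assert len(set(order[:k]) & var_groups) >= k - 1

    def test_adjustment_decorrelates_composition_and_variability(self):
        # groups differ in composition only: adjusted variability effects
        # should not track composition effects
        rs, cs = [], []
        for rep in range(3):
            table, truth = cb.simulate_scbb_dataset(
                n_groups=10, n_samples=16, cells_per_sample=1500,
                n_conditions=2, effect=1.0, frac_differential=0.4,
                seed=50 + rep)
            model = cb.CompositionModel.from_formula(
                table, "~ 1 + condition", "~ 1 + condition")
            res = model.fit(cb.McmcConfig(seed=60 + rep, **FAST_CFG))
            comp = res.test_composition("condition[B]")["effect_mean"]
            var = res.test_variability("condition[B]")["effect_mean"]
            cs.append(comp.to_numpy())
            rs.append(var.to_numpy())
        r = stats.pearsonr(np.concatenate(cs), np.concatenate(rs))[0]
        assert abs(r) < 0.35

    def test_equal_variability_yields_no_calls(self):
        table, _ = cb.simulate_scbb_dataset(
            n_groups=10, n_samples=20, cells_per_sample=2000,
            n_conditions=2, effect=1.0, frac_differential=0.4,
            variability_effect=0.0, frac_differential_variability=0.5,
            seed=71)
        model = cb.CompositionModel.from_formula(
            table, "~ 1 + condition", "~ 1 + condition")
        res = model.fit(cb.McmcConfig(seed=72, **FAST_CFG))
        tab = res.test_variability("condition[B]")
        assert tab["significant"].mean() <= 0.10


class TestMeanVariabilityScan:
    @pytest.fixture(scope="class")
    def scan(self):
        table, _ = cb.simulate_scbb_dataset(
            n_groups=14, n_samples=20, cells_per_sample=2000,
            lambda0=5.0, lambda1=-0.8, phi=0.3, gamma_sd=1.2, seed=81)
        return mean_variability_scan(table,
                                     config=cb.McmcConfig(seed=82,
                                                          **FAST_CFG),
                                     refit_hierarchical=True)

    def test_robust_line_recovers_slope(self, scan):
        assert -1.1 <= scan["line_slope"] <= -0.5

    def test_hierarchical_prior_shrinks_intervals(self, scan):
        ratios = scan["table"]["shrinkage_ratio"]
        assert np.median(ratios) > 1.0

    def test_mixture_assigns_offset_groups_to_minority(self):
        # two of twenty groups sit 2 log-units below the line: the
        # high-variability minority mode
        table, truth = cb.simulate_scbb_dataset(
            n_groups=20, n_samples=20, cells_per_sample=2000,
            lambda0=5.5, lambda1=-0.8, phi=0.25, seed=91)
        rng = np.random.default_rng(92)
        offset_groups = rng.choice(20, size=2, replace=False)
        state = truth.state
        omega = state.omega.copy()
        omega[offset_groups, 0] -= 2.0
        shifted = cb.RegressionState(Gamma=state.Gamma, omega=omega,
                                     lambda0=state.lambda0,
                                     lambda1=state.lambda1, phi=state.phi)
        design = cb.build_design(table, "~ 1")
        table2 = cb.simulate_scbb(shifted, design, design, table.totals,
                                  seed=93)
        out = mean_variability_scan(
            table2, config=cb.McmcConfig(seed=94, **FAST_CFG),
            mixture=True)
        p_min = out["table"]["p_minority_component"].to_numpy()
        top2 = np.argsort(p_min)[-2:]
        assert set(top2) == set(offset_groups)


class TestModelAdequacy:
    def test_scbb_calibrated_where_dirichlet_multinomial_is_not(self):
        # heteroscedastic compositional data (group-specific sigma on the
        # mean-variability line): the fitted model's rank-paired PPC slopes
        # show no abundance trend, while a single-precision Dirichlet-
        # multinomial oracle over-simulates the spread of rare groups and
        # under-simulates abundant ones
        table, truth = cb.simulate_scbb_dataset(
            n_groups=10, n_samples=40, cells_per_sample=1000,
            gamma_sd=1.3, phi=0.2, seed=101)
        res = cb.CompositionModel(table).fit(
            cb.McmcConfig(seed=102, **FAST_CFG))
        scbb_slopes = res.ppc(n_replicates=20, seed=103)
        scbb_trend = cb.ppc_slope_trend(scbb_slopes)
        lo, hi = scbb_trend["slope_ci"]
        assert lo <= 0 <= hi

        alpha = cb.fit_dirichlet_multinomial(table)
        sims = [cb.simulate_dirichlet_multinomial(
            alpha, table.n_samples, table.totals, seed=200 + r)[0]
            for r in range(20)]
        dm_slopes = cb.ppc_slopes(table, sims)
        dm_trend = cb.ppc_slope_trend(dm_slopes)
        assert dm_trend["slope"] < 0 and dm_trend["pvalue"] < 0.05
        merged = dm_slopes.sort_values("abundance")
        assert merged["slope"].iloc[0] > 1.0   # rarest over-dispersed
        assert merged["slope"].iloc[-1] < 1.0  # most abundant under-disp.


class TestHyperpriorTransfer:
    def test_learned_line_matches_generator(self, fitted, sim_dataset):
        _, truth = sim_dataset
        hp = fitted.learn_hyperpriors()
        # generating line: lambda0 = 5, lambda1 = -0.8
        assert abs(hp.lambda0_mean - truth.state.lambda0) <= \
            3 * hp.lambda0_sd + 0.5
        assert abs(hp.lambda1_mean - truth.state.lambda1) <= \
            3 * hp.lambda1_sd + 0.3
        m = hp.phi_shape / hp.phi_rate
        assert 0.1 < m < 1.5  # phi posterior mean on a sane scale

    def test_informative_hyperpriors_tighten_line_posterior(self,
                                                            fitted):
        hp = fitted.learn_hyperpriors()
        table, _ = cb.simulate_scbb_dataset(n_groups=6, n_samples=4,
                                            cells_per_sample=1000, seed=55)
        cfg = cb.McmcConfig(seed=56, **FAST_CFG)
        weak = cb.CompositionModel(table).fit(cfg)
        strong = cb.CompositionModel(table, hyperpriors=hp).fit(cfg)
        assert strong.posterior.lambda0.std() < weak.posterior.lambda0.std()
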