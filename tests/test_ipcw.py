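import numpy as np
import pandas as pd
import pytest

import panelcea as pc
from panelcea.grid import DAYS_PER_MONTH, DAYS_PER_YEAR
from panelcea.ipcw import (accrual_arrays, ipcw_weight_matrix,
                           ipcw_weights, matched_arm_frames,
                           weighted_totals, wls_incremental)
from panelcea.survival import reverse_km_censoring

from conftest import make_arm_frame


class TestGrid:
    def test_zero_rate_unit_factors(self):
        g = pc.build_grid(3, 0.0)
        assert np.allclose(g.discount_factors, 1.0)

    def test_one_year_interval_factor(self):
        g = pc.build_grid(3, 0.015)
        # interval 13 starts exactly at 365.25 days -> factor 1/1.015
        assert np.isclose(g.start_days[12], 365.25)
        assert np.isclose(g.discount_factors[12], 1.0 / 1.015)

    def test_three_year_horizon_length(self):
        g = pc.build_grid(3)
        assert g.n_intervals == 36
        assert np.isclose(g.horizon_days, 1095.75)

    def test_factors_nonincreasing(self):
        g = pc.build_grid(3, 0.03)
        assert np.all(np.diff(g.discount_factors) <= 0)


class TestWeights:
    def test_no_censoring_all_weights_one(self):
        df = make_arm_frame([500.0, 800.0, 1200.0], "death")
        g = pc.build_grid(3, 0.0)
        W, include = ipcw_weights(df, g)
        assert np.allclose(W[include], 1.0)

    def test_half_survival_gives_weight_two(self):
        # 10 patients: 5 censored at day 100, 5 observed far beyond;
        # G(100) = 1/2 so later interval starts carry weight 2
        days = [100.0] * 5 + [1000.0] * 5
        ev = ["censored"] * 5 + ["death"] * 5
        df = make_arm_frame(days, ev)
        g = pc.build_grid(3)
        W, include = ipcw_weights(df, g)
        j = 5   # month-6 start = 152.2 d > 100
        assert np.allclose(W[5:, j], 2.0)
        assert not include[:5, j].any()

    def test_toy_hand_oracle(self, toy_survival):
        # hand product-limit: G = 1 before day 200, 2/3 from 200 on;
        # month ends 182.6 (j=6) and 213.1 (j=7) bracket the censoring
        times, events = toy_survival
        df = make_arm_frame(times, events)
        g = pc.build_grid(3)
        W, include = ipcw_weights(df, g)
        # patient dying at 400: weight 1/G(min(400, end_j)-)
        assert np.allclose(W[3, :6], 1.0)
        assert np.allclose(W[3, 6:], 1.5)
        # patient dying at 100: weight from death time, G(100-) = 1
        assert np.allclose(W[0, include[0]], 1.0)
        assert include[0].all()                    # zero-accrual retained
        # censored at 200: contributes only fully-observed intervals
        assert include[1, :6].all() and not include[1, 6:].any()
        assert np.allclose(W[1, :6], 1.0)
        # patient dying at 300: 1/G(min(300, end_j)-)
        assert np.allclose(W[2, :6], 1.0)
        assert np.allclose(W[2, 6:], 1.5)

    def test_ghat_zero_with_patient_observed_errors(self):
        df = make_arm_frame([100.0, 100.0, 900.0],
                            ["censored", "censored", "death"])
        g = pc.build_grid(3)
        X = df["observed_time_days"].to_numpy()
        death = (df["event"] == "death").to_numpy()
        ghat = reverse_km_censoring(X[:2], np.zeros(2, bool))  # G -> 0
        with pytest.raises(ValueError, match="G-hat"):
            ipcw_weight_matrix(X, death, g, ghat)


class TestWeightedTotals:
    def test_single_patient_full_horizon(self):
        df = make_arm_frame([2000.0], "death", monthly_cost=100.0)
        tot = weighted_totals(df, pc.build_grid(3, 0.0))
        assert np.isclose(tot.mean_cost, 3600.0)
        assert np.isclose(tot.mean_ly, 3.0)

    def test_death_at_interval_boundary(self):
        df = make_arm_frame([12 * DAYS_PER_MONTH], "death")
        tot = weighted_totals(df, pc.build_grid(3, 0.0))
        assert np.isclose(tot.mean_ly, 1.0)

    def test_zero_censoring_equals_naive_mean(self):
        cfg = pc.default_config(
            n_patients=400, seed=20,
            censoring=pc.synthetic.CensoringModel(
                accrual_window_days=0.0, admin_cutoff_days=1e9,
                dropout_rate_per_year=0.0, max_followup_days=1e9))
        coh = pc.generate_cohort(cfg)
        g = pc.build_grid(3, 0.015)
        for arm in ("treated", "control"):
            df = coh.data[coh.data.arm == arm].reset_index()
            tot = weighted_totals(df, g)
            costs, alive, _, _ = accrual_arrays(df, g)
            naive_cost = (costs * g.discount_factors).sum(axis=1).mean()
            naive_ly = ((alive * g.discount_factors).sum(axis=1)
                        / DAYS_PER_YEAR).mean()
            assert np.isclose(tot.mean_cost, naive_cost, rtol=1e-10)
            assert np.isclose(tot.mean_ly, naive_ly, rtol=1e-10)

    def test_ipcw_corrects_complete_case_bias(self):
        # informative-by-construction censoring of the cost trajectory:
        # IPCW recovers the uncensored-world mean, the complete-case
        # analysis does not (single large cohort)
        base = pc.default_config(n_patients=8000, seed=21,
                                 assignment_coefficients={})
        nocens = pc.synthetic.CensoringModel(
            accrual_window_days=0.0, admin_cutoff_days=1e9,
            dropout_rate_per_year=0.0, max_followup_days=1e9)
        import dataclasses
        truth_coh = pc.generate_cohort(
            dataclasses.replace(base, censoring=nocens))
        g = pc.build_grid(3, 0.0)
        dfT = truth_coh.data[truth_coh.data.arm == "control"].reset_index()
        costsT, _, _, _ = accrual_arrays(dfT, g)
        truth = (costsT * g.discount_factors).sum(axis=1).mean()

        coh = pc.generate_cohort(base)
        df = coh.data[coh.data.arm == "control"].reset_index()
        tot = weighted_totals(df, g)
        costs, _, X, death = accrual_arrays(df, g)
        complete = death | (X >= g.horizon_days)
        naive = (costs[complete] * g.discount_factors).sum(axis=1).mean()
        assert abs(tot.mean_cost - truth) < abs(naive - truth)


class TestIncremental:
    def test_identical_arms_zero_deltas(self):
        df = make_arm_frame([500.0, 700.0, 900.0],
                            ["death", "censored", "death"])
        g = pc.build_grid(3)
        tot = weighted_totals(df, g)
        est = pc.incremental_estimates(tot, tot)
        assert est.delta_c == 0.0 and est.delta_e == 0.0

    def test_regression_path_equals_weighted_means(self, small_cohort,
                                                   small_match):
        g = pc.build_grid(3)
        df_t, df_c = matched_arm_frames(small_cohort, small_match)
        tot_t, tot_c = weighted_totals(df_t, g), weighted_totals(df_c, g)
        est = pc.incremental_estimates(tot_t, tot_c)
        dc, de = wls_incremental(df_t, df_c, g)
        assert np.isclose(dc, est.delta_c, rtol=1e-9)
        assert np.isclose(de, est.delta_e, rtol=1e-9, atol=1e-10)

    def test_horizon_nesting(self, small_cohort, small_match):
        df_t, _ = matched_arm_frames(small_cohort, small_match)
        g3 = pc.build_grid(3, 0.015)
        g1 = pc.build_grid(1, 0.015)
        t3 = weighted_totals(df_t, g3)
        t1 = weighted_totals(df_t, g1)
        # first 12 interval means and discount factors coincide
        assert np.allclose(t1.interval_cost_means,
                           t3.interval_cost_means[:12])
        assert np.isclose(
            t1.mean_cost,
            (g3.discount_factors[:12] * t3.interval_cost_means[:12]).sum())

    def test_discount_monotone(self, small_cohort, small_match):
        df_t, _ = matched_arm_frames(small_cohort, small_match)
        vals = [weighted_totals(df_t, pc.build_grid(3, r)).mean_cost
                for r in (0.0, 0.015, 0.05, 0.10)]
        assert np.all(np.diff(vals) <= 0)


class TestSUR:
    @staticmethod
    def _correlated_cohort(rho, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        cov = [[1.0, rho], [rho, 1.0]]
        u, v = rng.multivariate_normal([0, 0], cov, size=n).T
        T = np.clip(500.0 + 120.0 * u, 30.0, 1090.0)
        df = make_arm_frame(T, "death", monthly_cost=0.0)
        df["cost_m01"] = 50_000.0 + 5_000.0 * v
        return df

    @staticmethod
    def _to_match(df_t, df_c):
        from panelcea.matching import MatchResult
        from panelcea.synthetic import CohortTable, CovariateSpec
        df_c = df_c.copy()
        df_c["arm"] = "control"
        df_c["id"] = df_c["id"] + 1_000_000
        both = pd.concat([df_t, df_c], ignore_index=True)
        both["dummy"] = 0.0
        coh = CohortTable(both, (CovariateSpec("dummy", "binary",
                                               {"p": 0.5}),))
        pairs = list(zip(df_t.id, df_c.id))
        return coh, MatchResult(pairs=pairs,
                                distances=np.zeros(len(pairs)),
                                weight_vector={}, fitness_trace=[],
                                n_matched=len(pairs), n_treated=len(pairs),
                                strata_map={})

    @pytest.mark.parametrize("rho", [0.5, 0.0])
    def test_residual_correlation_recovery(self, rho):
        df_t = self._correlated_cohort(rho, seed=1)
        df_c = self._correlated_cohort(rho, seed=2)
        coh, match = self._to_match(df_t, df_c)
        g = pc.build_grid(3, 0.0)
        est = pc.sur_estimates(coh, match, g)
        assert abs(est.residual_correlation - rho) < 0.06

    def test_point_estimates_equal_single_equation_path(self, small_cohort,
                                                        small_match):
        g = pc.build_grid(3)
        est_sur = pc.sur_estimates(small_cohort, small_match, g)
        df_t, df_c = matched_arm_frames(small_cohort, small_match)
        est = pc.incremental_estimates(weighted_totals(df_t, g),
                                       weighted_totals(df_c, g))
        assert est_sur.delta_c == est.delta_c
        assert est_sur.delta_e == est.delta_e
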