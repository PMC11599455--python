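import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import logit

import panelcea as pc
from panelcea.matching import _ks_statistic, ks_boot, match_with_weights
from panelcea.synthetic import CohortTable, CovariateSpec


def make_binary_cohort(n00, n01, n10, n11):
    """Cohort with one binary covariate x; counts (arm, x) -> n."""
    rows = []
    for arm, x, n in (("control", 0, n00), ("treated", 0, n01),
                      ("control", 1, n10), ("treated", 1, n11)):
        rows += [{"arm": arm, "x": float(x)}] * n
    df = pd.DataFrame(rows)
    df.insert(0, "id", np.arange(len(df)))
    specs = (CovariateSpec("x", "binary", {"p": 0.5}),)
    return CohortTable(data=df, covariate_specs=specs)


class TestPropensity:
    def test_null_model_returns_treated_fraction(self):
        rng = np.random.default_rng(0)
        n = 4000
        df = pd.DataFrame({"id": np.arange(n),
                           "arm": np.where(rng.random(n) < 0.4, "treated",
                                           "control"),
                           "x": rng.normal(size=n)})
        coh = CohortTable(df, (CovariateSpec("x", "continuous",
                                             {"dist": "normal", "mean": 0,
                                              "sd": 1}),))
        p = pc.estimate_propensity(coh)
        frac = coh.arm_bool.mean()
        assert np.allclose(p, frac, atol=0.05)

    def test_saturated_two_by_two_log_odds(self):
        # cells: x=0 -> 40 control/10 treated; x=1 -> 10 control/40 treated
        coh = make_binary_cohort(40, 10, 10, 40)
        p = pc.estimate_propensity(coh)
        x = coh.data["x"].to_numpy()
        log_or = logit(p[x == 1][0]) - logit(p[x == 0][0])
        assert np.isclose(log_or, np.log(16.0), atol=1e-4)

    def test_perfect_separation_clips_and_warns(self):
        coh = make_binary_cohort(50, 0, 0, 50)
        with pytest.warns(UserWarning, match="separat"):
            p = pc.estimate_propensity(coh)
        assert p.min() >= 1e-6 and p.max() <= 1 - 1e-6


class TestGeneralizedDistance:
    def test_reduces_to_euclidean(self):
        chol_inv = np.eye(2)
        w = np.ones(2)
        d = pc.generalized_distance([1.0, 2.0], [4.0, 6.0], chol_inv, w)
        assert np.isclose(d, 5.0)

    def test_zero_iff_equal(self):
        chol_inv = np.linalg.inv(np.linalg.cholesky([[2.0, 0.3],
                                                     [0.3, 1.0]]))
        assert pc.generalized_distance([1, 2], [1, 2], chol_inv,
                                       [3.0, 0.5]) == 0.0

    def test_matches_brute_force_quadratic_form(self):
        cov = np.array([[4.0, 1.0], [1.0, 2.0]])
        L = np.linalg.cholesky(cov)
        chol_inv = np.linalg.inv(L)
        w = np.array([2.0, 0.5])
        xi, xj = np.array([1.0, -1.0]), np.array([0.5, 2.0])
        delta = xi - xj
        M = chol_inv.T @ np.diag(w) @ chol_inv
        expect = np.sqrt(delta @ M @ delta)
        assert np.isclose(pc.generalized_distance(xi, xj, chol_inv, w),
                          expect)

    def test_rejects_nonpositive_weights(self):
        with pytest.raises(ValueError):
            pc.generalized_distance([1.0], [0.0], np.eye(1), [0.0])


def _two_group_cohort(treated_x, control_x, exact=None):
    nt, nc = len(treated_x), len(control_x)
    df = pd.DataFrame({
        "id": np.arange(nt + nc),
        "arm": ["treated"] * nt + ["control"] * nc,
        "x": np.concatenate([treated_x, control_x]).astype(float),
    })
    if exact is not None:
        df["g"] = exact
    specs = [CovariateSpec("x", "continuous",
                           {"dist": "normal", "mean": 0, "sd": 1})]
    if exact is not None:
        specs.append(CovariateSpec("g", "binary", {"p": 0.5},
                                   exact_match=True))
    return CohortTable(df, tuple(specs))


class TestMatchWithWeights:
    CFG = pc.MatchingConfig(include_propensity=False, population_size=8,
                            seed=1)

    def test_identical_twins_all_distance_zero(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        coh = _two_group_cohort(vals, vals[::-1])
        res = match_with_weights(coh, np.ones(1), self.CFG)
        assert res.n_matched == 4
        assert np.allclose(res.distances, 0.0)

    def test_control_exhaustion_without_replacement(self):
        coh = _two_group_cohort([1.0, 1.1], [1.05])
        res = match_with_weights(coh, np.ones(1), self.CFG)
        assert res.n_matched == 1

    def test_capped_replacement_limits_reuse(self):
        # one attractive control at 0; four treated at ~0; cap 3
        cfg = pc.MatchingConfig(include_propensity=False, population_size=8,
                                replacement_mode=("capped", 3), seed=1)
        coh = _two_group_cohort([0.0, 0.01, -0.01, 0.02],
                                [0.0, 100.0, 101.0])
        res = match_with_weights(coh, np.ones(1), cfg)
        counts = pd.Series(res.control_ids()).value_counts()
        near = coh.data[np.isclose(coh.data.x, 0.0)
                        & (coh.data.arm == "control")].id.iloc[0]
        assert counts[near] == 3
        assert res.n_matched == 4

    def test_exact_strata_respected(self):
        coh = _two_group_cohort([0.0, 0.0], [0.0, 0.0],
                                exact=[0, 1, 1, 0])
        res = match_with_weights(coh, np.ones(1), self.CFG)
        g = coh.data.set_index("id")["g"]
        for t, c in res.pairs:
            assert g[t] == g[c]


class TestBalanceFitness:
    def test_exactly_matched_pairs_give_unit_pvalues(self):
        vals = np.linspace(-2, 2, 30)
        coh = _two_group_cohort(vals, vals)
        cfg = pc.MatchingConfig(include_propensity=False, population_size=8,
                                ks_boot_reps=100, seed=2)
        res = match_with_weights(coh, np.ones(1), cfg)
        p = pc.balance_fitness(res, coh, cfg)
        assert np.allclose(res.distances, 0.0)
        assert np.all(p == 1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        t = rng.normal(3.0, 1.0, 400)
        c = rng.normal(0.0, 1.0, 400)
        coh = _two_group_cohort(t, c)
        cfg = pc.MatchingConfig(include_propensity=False, population_size=8,
                                ks_boot_reps=2000, seed=3)
        res = match_with_weights(coh, np.ones(1), cfg)
        p = pc.balance_fitness(res, coh, cfg)
        assert p.min() < 0.001

    def test_ks_boot_statistic_matches_scipy(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=80), rng.normal(0.4, 1.2, size=120)
        stat, _ = ks_boot(x, y, 50, rng)
        assert np.isclose(stat, stats.ks_2samp(x, y).statistic)
        # and on tied data
        xi = rng.integers(0, 4, 60).astype(float)
        yi = rng.integers(0, 4, 60).astype(float)
        assert np.isclose(_ks_statistic(xi, yi),
                          stats.ks_2samp(xi, yi).statistic)

    def test_doubling_reps_keeps_statistic_fixed(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=100), rng.normal(0.2, 1, 100)
        s1, p1 = ks_boot(x, y, 300, np.random.default_rng(6))
        s2, p2 = ks_boot(x, y, 600, np.random.default_rng(6))
        assert s1 == s2
        assert abs(p1 - p2) < 3 * np.sqrt(p1 * (1 - p1) / 300 + 1e-6)


class TestLexicalCompare:
    @pytest.mark.parametrize("a,b,expect", [
        ((0.01, 0.9), (0.02, 0.1), "b_better"),
        ((0.05, 0.2, 0.9), (0.05, 0.3, 0.1), "b_better"),
        ((0.5, 0.6), (0.5, 0.6), "tie"),
        ((0.3, 0.4), (0.2, 0.9), "a_better"),
    ])
    def test_rule(self, a, b, expect):
        assert pc.lexical_compare(np.array(a), np.array(b)) == expect


class TestGeneticSearch:
    def test_zero_generations_returns_all_ones_weights(self, small_cohort):
        cfg = pc.MatchingConfig(population_size=8, max_generations=0,
                                ks_boot_reps=50, seed=9)
        res = pc.genetic_search(small_cohort, cfg)
        assert np.allclose(list(res.weight_vector.values()), 1.0)
        assert res.n_matched > 0

    def test_small_population_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="population_size"):
            pc.genetic_search(small_cohort,
                              pc.MatchingConfig(population_size=4))

    def test_elitism_fitness_nondecreasing(self, small_match):
        trace = small_match.fitness_trace
        for a, b in zip(trace, trace[1:]):
            assert pc.lexical_compare(b, a) in ("a_better", "tie")

    def test_no_control_reuse_without_replacement(self, small_match):
        cids = small_match.control_ids()
        assert len(cids) == len(set(cids))

    def test_pairs_share_exact_covariates(self, small_cohort, small_match):
        d = small_cohort.data.set_index("id")
        for name in ("prior_lines", "prior_surgery", "region_vch"):
            t = d.loc[small_match.treated_ids(), name].to_numpy()
            c = d.loc[small_match.control_ids(), name].to_numpy()
            assert (t == c).all()

    def test_search_improves_confounded_covariate(self):
        cfg = pc.default_config(n_patients=700, seed=10)
        coh = pc.generate_cohort(cfg)
        mcfg = pc.MatchingConfig(population_size=10, max_generations=4,
                                 ks_boot_reps=80, seed=11)
        res = pc.genetic_search(coh, mcfg)
        bal = pc.balance_report(coh, res, mcfg)
        age = bal[bal.covariate == "age"].iloc[0]
        assert age.smd_matched < age.smd_unmatched

    def test_reproducible_under_seed(self, small_cohort, tiny_match_config,
                                     small_match):
        res2 = pc.genetic_search(small_cohort, tiny_match_config)
        assert res2.pairs == small_match.pairs
        assert res2.weight_vector == small_match.weight_vector
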