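"""Genetic-algorithm 1:1 covariate matching.

Treated patients are matched to controls by greedy nearest-neighbour search
on a generalized weighted Mahalanobis distance, constrained to exact-matching
strata.  A genetic algorithm evolves the per-covariate weight vector to
lexically maximise the sorted vector of post-match balance p-values
(bootstrapped Kolmogorov-Smirnov tests for continuous covariates, paired
t-tests for binary ones) -- balance itself, not a parametric propensity
model, is the optimisation target.  The fitted propensity score can be
appended as an extra matching covariate and informs the initial population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from panelcea.synthetic import CohortTable, design_matrix

PROPENSITY_CLIP = 1e-6


@dataclass(frozen=True)
class MatchingConfig:
    """Settings for genetic matching.

    replacement_mode is 'none' (each control used at most once) or
    ('capped', k) allowing each control up to k uses.
    """

    include_propensity: bool = True
    replacement_mode: object = "none"
    population_size: int = 100
    max_generations: int = 30
    stall_generations: int = 8
    ks_boot_reps: int = 300
    weight_bounds: tuple = (1e-3, 1e3)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.weight_bounds
        if lo <= 0 or hi <= lo:
            raise ValueError("weight_bounds must satisfy 0 < low < high")
        if self.replacement_mode != "none":
            mode, k = self.replacement_mode
            if mode != "capped" or k < 1:
                raise ValueError("replacement_mode must be 'none' or "
                                 "('capped', k>=1)")

    @property
    def replacement_cap(self) -> int | None:
        if self.replacement_mode == "none":
            return 1
        return int(self.replacement_mode[1])


@dataclass
class MatchResult:
    """Matched pairs plus the weight vector that produced them."""

    pairs: list                      # [(treated_id, control_id), ...]
    distances: np.ndarray            # distance per pair
    weight_vector: dict              # matching-covariate name -> weight
    fitness_trace: list              # best sorted p-vector per generation
    n_matched: int
    n_treated: int
    strata_map: dict                 # patient id -> stratum key

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n_treated

    def treated_ids(self) -> np.ndarray:
        return np.array([t for t, _ in self.pairs])

    def control_ids(self) -> np.ndarray:
        return np.array([c for _, c in self.pairs])


# ---------------------------------------------------------------------------
# propensity score

def estimate_propensity(cohort: CohortTable,
                        covariate_names: list | None = None) -> np.ndarray:
    """Logistic-regression propensity of treatment given covariates.

    Returns fitted probabilities clipped to (0,1); warns if more than 1% of
    patients sit at the clipping bounds (near-separation).
    """
    specs = [s for s in cohort.covariate_specs
             if covariate_names is None or s.name in covariate_names]
    if not specs:
        raise ValueError("no covariates selected")
    y = cohort.arm_bool.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both arms must be nonempty")
    X, names = design_matrix(cohort.data, specs)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("design matrix not full rank after one-hot expansion")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xc, family=sm.families.Binomial())
        fit = model.fit(maxiter=200)
    p = np.asarray(fit.predict(Xc))
    at_bound = (p < PROPENSITY_CLIP) | (p > 1 - PROPENSITY_CLIP)
    if at_bound.mean() > 0.01:
        warnings.warn("propensity model is near-separated; probabilities "
                      "clipped", stacklevel=2)
    return np.clip(p, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP)


def _propensity_coefs(cohort: CohortTable, specs) -> np.ndarray:
    """|coef| * sd of each design column, for initial-population jitter."""
    y = cohort.arm_bool.astype(float)
    X, _ = design_matrix(cohort.data, specs)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=200)
    beta = np.asarray(fit.params)[1:]
    return np.abs(beta) * X.std(axis=0)


# ---------------------------------------------------------------------------
# distance

def _inverse_cholesky(cov: np.ndarray) -> np.ndarray:
    """Inverse Cholesky factor of a covariance; ridge-regularised if needed."""
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; adding ridge 1e-8*I",
                      stacklevel=2)
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(cov)))
    return np.linalg.inv(L)


def generalized_distance(x_i: np.ndarray, x_j: np.ndarray,
                         chol_inv: np.ndarray, w: np.ndarray) -> float:
    """Generalized weighted Mahalanobis distance between two patients.

    d = sqrt((x_i-x_j)' chol_inv' diag(w) chol_inv (x_i-x_j)) where chol_inv
    is the inverse Cholesky factor of the pooled pre-match covariance.  With
    w = 1 this is the ordinary Mahalanobis distance; with identity
    covariance as well, the Euclidean distance.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    z = chol_inv @ (np.asarray(x_i, float) - np.asarray(x_j, float))
    return float(np.sqrt(np.sum(w * z * z)))


# ---------------------------------------------------------------------------
# precomputed matching data

class MatchingData:
    """Whitened covariates, strata and balance columns for one cohort.

    Built once per cohort+config; every weight-vector evaluation (there are
    thousands during a genetic search) reuses these arrays.
    """

    def __init__(self, cohort: CohortTable, config: MatchingConfig):
        self.cohort = cohort
        self.config = config
        specs = cohort.covariate_specs
        self.exact_names = [s.name for s in specs if s.exact_match]
        dist_specs = [s for s in specs if not s.exact_match]

        X, names = design_matrix(cohort.data, dist_specs)
        if config.include_propensity:
            ps = estimate_propensity(cohort)
            X = np.column_stack([X, ps])
            names = names + ["propensity"]
        self.matching_names = names
        cov = np.cov(X, rowvar=False)
        self.chol_inv = _inverse_cholesky(np.atleast_2d(cov))
        self.Z = X @ self.chol_inv.T
        self.n_dims = self.Z.shape[1]

        self.ids = cohort.data["id"].to_numpy()
        self.treated_mask = cohort.arm_bool
        if self.exact_names:
            keys = cohort.data[self.exact_names].astype(str).agg(
                "|".join, axis=1).to_numpy()
        else:
            keys = np.array(["all"] * cohort.n)
        self.stratum_keys = keys
        self.strata_map = dict(zip(self.ids.tolist(), keys.tolist()))

        tr_idx = np.flatnonzero(self.treated_mask)
        co_idx = np.flatnonzero(~self.treated_mask)
        self.treated_idx = tr_idx
        # controls grouped by stratum for fast candidate lookup
        self.controls_by_stratum = {}
        for key in np.unique(keys):
            self.controls_by_stratum[key] = co_idx[keys[co_idx] == key]

        # balance columns: configured covariates (one-hot) + squared age and
        # an age x sex interaction where those covariates exist
        Xb, bnames = design_matrix(cohort.data, specs)
        bkinds = []
        for s in specs:
            if s.kind == "categorical":
                bkinds += ["binary"] * (len(s.params["levels"]) - 1)
            else:
                bkinds.append(s.kind)
        cols = [Xb[:, k] for k in range(Xb.shape[1])]
        if "age" in bnames:
            age = Xb[:, bnames.index("age")]
            cols.append(age ** 2)
            bnames = bnames + ["age^2"]
            bkinds = bkinds + ["continuous"]
            if "sex_male" in bnames:
                sex = Xb[:, bnames.index("sex_male")]
                cols.append(age * sex)
                bnames = bnames + ["age*sex_male"]
                bkinds = bkinds + ["continuous"]
        self.balance_matrix = np.column_stack(cols)
        self.balance_names = bnames
        self.balance_kinds = bkinds

        # propensity-informed jitter scale for the initial population
        scale = np.ones(self.n_dims)
        if config.include_propensity:
            coefs = _propensity_coefs(cohort, dist_specs)
            if coefs.max() > 0:
                scale[:len(coefs)] += coefs / coefs.max()
        self.init_jitter_scale = scale


# ---------------------------------------------------------------------------
# greedy nearest-neighbour matching

def _greedy_match(data: MatchingData, w: np.ndarray,
                  rng: np.random.Generator):
    """Greedy in-stratum nearest neighbour in randomized treated order.

    Ties in distance are broken by a seeded random choice among the
    equidistant controls.  Returns (treated_idx, control_idx, distances).
    """
    cap = data.config.replacement_cap
    uses = np.zeros(data.cohort.n, dtype=int)
    order = rng.permutation(data.treated_idx)
    avail = {k: list(v) for k, v in data.controls_by_stratum.items()}
    t_out, c_out, d_out = [], [], []
    Z = data.Z
    for i in order:
        cands = avail.get(data.stratum_keys[i])
        if not cands:
            continue
        cand = np.asarray(cands)
        diff = Z[cand] - Z[i]
        d2 = (diff * diff * w).sum(axis=1)
        dmin = d2.min()
        tie = np.flatnonzero(d2 <= dmin + 1e-12 * (1.0 + dmin))
        pick = tie[0] if len(tie) == 1 else rng.choice(tie)
        j = int(cand[pick])
        t_out.append(int(i))
        c_out.append(j)
        d_out.append(float(np.sqrt(max(d2[pick], 0.0))))
        uses[j] += 1
        if uses[j] >= cap:
            cands.remove(j)
    return (np.array(t_out, dtype=int), np.array(c_out, dtype=int),
            np.array(d_out))


def match_with_weights(cohort: CohortTable, w: np.ndarray,
                       config: MatchingConfig,
                       data: MatchingData | None = None) -> MatchResult:
    """Match treated to controls under a fixed weight vector."""
    if data is None:
        data = MatchingData(cohort, config)
    w = np.asarray(w, dtype=float)
    if w.shape != (data.n_dims,):
        raise ValueError(f"weight vector must have length {data.n_dims}")
    rng = np.random.default_rng([config.seed, 7_001])
    ti, ci, d = _greedy_match(data, w, rng)
    pairs = list(zip(data.ids[ti].tolist(), data.ids[ci].tolist()))
    return MatchResult(
        pairs=pairs, distances=d,
        weight_vector=dict(zip(data.matching_names, w.tolist())),
        fitness_trace=[], n_matched=len(pairs),
        n_treated=len(data.treated_idx), strata_map=data.strata_map)


# ---------------------------------------------------------------------------
# balance fitness

def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic, ties evaluated at distinct values only."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    grid.sort(kind="mergesort")
    ca = np.searchsorted(a, grid, side="right") / len(a)
    cb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.abs(ca - cb).max())


def ks_boot(x: np.ndarray, y: np.ndarray, nboots: int,
            rng: np.random.Generator) -> tuple[float, float]:
    """Bootstrapped two-sample KS test (pooled-resample null).

    Resamples both samples with replacement from the pooled values and
    returns (observed statistic, p = fraction of bootstrap statistics >=
    observed).  Robust to heavily tied data, where the asymptotic KS p-value
    is not.
    """
    n1, n2 = len(x), len(y)
    obs = _ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    idx = rng.integers(0, n1 + n2, size=(nboots, n1 + n2))
    v = pooled[idx]
    a = np.sort(v[:, :n1], axis=1)
    b = np.sort(v[:, n1:], axis=1)
    # batched KS via signed step heights on the row-sorted pooled order
    vv = np.concatenate([a, b], axis=1)
    step = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    order = np.argsort(vv, axis=1, kind="mergesort")
    svals = np.take_along_axis(vv, order, axis=1)
    ssteps = np.broadcast_to(step, vv.shape)
    ssteps = np.take_along_axis(ssteps, order, axis=1)
    cum = np.cumsum(ssteps, axis=1)
    distinct = np.ones_like(svals, dtype=bool)
    distinct[:, :-1] = svals[:, 1:] != svals[:, :-1]
    stats_b = np.where(distinct, np.abs(cum), 0.0).max(axis=1)
    p = float(np.mean(stats_b >= obs - 1e-12))
    return obs, p


def _paired_t_p(diffs: np.ndarray) -> float:
    if np.all(diffs == 0):
        return 1.0
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 0.0
    t = diffs.mean() / (sd / np.sqrt(len(diffs)))
    return float(2 * stats.t.sf(abs(t), len(diffs) - 1))


def balance_fitness(matched: MatchResult, cohort: CohortTable,
                    config: MatchingConfig,
                    data: MatchingData | None = None) -> np.ndarray:
    """Sorted ascending vector of post-match balance p-values.

    Continuous balance terms use the bootstrapped KS test; binary terms use
    a paired t-test on within-pair differences.  The bootstrap resample
    stream is re-seeded from the config so repeated evaluations during a
    genetic search see a common-random-numbers fitness surface.
    """
    if matched.n_matched < 10:
        raise ValueError("need at least 10 matched pairs for balance tests")
    if data is None:
        data = MatchingData(cohort, config)
    id_pos = {int(i): k for k, i in enumerate(data.ids)}
    ti = np.array([id_pos[t] for t, _ in matched.pairs])
    ci = np.array([id_pos[c] for _, c in matched.pairs])
    rng = np.random.default_rng([config.seed, 7_002])
    pvals = []
    for k, kind in enumerate(data.balance_kinds):
        xt = data.balance_matrix[ti, k]
        xc = data.balance_matrix[ci, k]
        if kind == "binary":
            pvals.append(_paired_t_p(xt - xc))
        else:
            _, p = ks_boot(xt, xc, config.ks_boot_reps, rng)
            pvals.append(p)
    return np.sort(np.asarray(pvals))


def lexical_compare(p_a: np.ndarray, p_b: np.ndarray) -> str:
    """Compare sorted p-value vectors: larger p at the first differing index
    (from the worst-balanced end) wins; returns 'a_better', 'b_better' or
    'tie'."""
    p_a = np.asarray(p_a)
    p_b = np.asarray(p_b)
    if p_a.shape != p_b.shape:
        raise ValueError("p-value vectors must have equal length")
    diff = np.flatnonzero(p_a != p_b)
    if len(diff) == 0:
        return "tie"
    k = diff[0]
    return "a_better" if p_a[k] > p_b[k] else "b_better"


# ---------------------------------------------------------------------------
# genetic search

def genetic_search(cohort: CohortTable,
                   config: MatchingConfig | None = None) -> MatchResult:
    """Evolve matching weights to lexically maximise post-match balance.

    Generation loop: evaluate the balance fitness of the match each weight
    vector induces, rank by lexical comparison, keep the best unchanged
    (elitism), and refill the population by tournament selection, log-space
    blend crossover and multiplicative lognormal mutation.  Stops after
    ``max_generations`` or ``stall_generations`` without lexical improvement.
    Fully reproducible under ``config.seed``.
    """
    if config is None:
        config = MatchingConfig()
    if config.population_size < 8:
        raise ValueError("population_size must be >= 8")
    data = MatchingData(cohort, config)
    rng = np.random.default_rng([config.seed, 7_000])
    lo, hi = config.weight_bounds
    d = data.n_dims
    npop = config.population_size

    def evaluate(w):
        res = match_with_weights(cohort, w, config, data)
        fit = balance_fitness(res, cohort, config, data)
        return res, fit

    # initial population: all-ones plus propensity-informed lognormal jitter
    pop = [np.ones(d)]
    for _ in range(npop - 1):
        jitter = rng.normal(0.0, 0.4 * data.init_jitter_scale)
        pop.append(np.clip(np.exp(jitter), lo, hi))

    best_w, best_fit, best_res = None, None, None
    trace = []
    stall = 0

    def better(fa, fb):   # is fa lexically better than fb?
        return fb is None or lexical_compare(fa, fb) == "a_better"

    for gen in range(max(config.max_generations, 1)):
        scored = []
        for w in pop:
            res, fit = evaluate(w)
            scored.append((w, fit, res))
        scored.sort(key=lambda s: tuple(s[1]), reverse=True)
        gen_best = scored[0]
        improved = better(gen_best[1], best_fit)
        if improved:
            best_w, best_fit, best_res = gen_best
            stall = 0
        else:
            stall += 1
        trace.append(np.asarray(best_fit).copy())
        if config.max_generations == 0:
            break
        if gen == config.max_generations - 1 or stall >= config.stall_generations:
            break

        def tournament():
            picks = rng.integers(0, npop, 3)
            k = min(picks)          # scored is sorted best-first
            return scored[k][0]

        children = [best_w.copy()]  # elitism
        while len(children) < npop:
            pa, pb = tournament(), tournament()
            u = rng.random(d)
            child = np.exp(u * np.log(pa) + (1 - u) * np.log(pb))
            mutate = rng.random(d) < 0.3
            child = child * np.where(mutate,
                                     np.exp(rng.normal(0.0, 0.35, d)), 1.0)
            children.append(np.clip(child, lo, hi))
        pop = children

    if config.max_generations == 0:
        # no evolution: return the match under all-ones weights
        w0 = np.ones(d)
        best_res, best_fit = evaluate(w0)
        best_w = w0
        trace = [np.asarray(best_fit).copy()]

    best_res.weight_vector = dict(zip(data.matching_names, best_w.tolist()))
    best_res.fitness_trace = trace
    _assert_replacement_invariant(best_res, config)
    return best_res


def _assert_replacement_invariant(res: MatchResult,
                                  config: MatchingConfig) -> None:
    ids, counts = np.unique(res.control_ids(), return_counts=True)
    cap = config.replacement_cap
    if len(ids) and counts.max() > cap:
        raise AssertionError(
            f"control reused {counts.max()} times, cap is {cap}")
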