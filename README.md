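# panelcea

Real-world cost-effectiveness analysis of multi-gene panel sequencing
versus single-gene EGFR testing for advanced non-small-cell lung cancer,
as a reusable, tested Python pipeline.

Observational comparisons of tumour-testing strategies face three linked
problems: test assignment is confounded by patient characteristics,
follow-up is right-censored (so naive means of costs and survival are
biased), and the decision quantity — is the more expensive test worth it?
— needs a joint sampling distribution of incremental costs and effects.
`panelcea` addresses all three:

- **Genetic matching** (`panelcea.matching`): 1:1 nearest-neighbour
  matching on a generalized weighted Mahalanobis distance
  d(i,j) = √((xᵢ−xⱼ)ᵀL⁻ᵀ diag(w) L⁻¹(xᵢ−xⱼ)) within exact-matching
  strata, with the weight vector w evolved by a genetic algorithm to
  lexically maximise the sorted vector of balance p-values (bootstrapped
  Kolmogorov–Smirnov for continuous covariates, paired t for binary).
- **Balance diagnostics** (`panelcea.balance`): standardized mean
  differences against the pooled pre-match SD, orientation-free variance
  ratios, KS statistics; adequacy = all SMD < 0.1 and VR < 2.
- **Survival models** (`panelcea.survival`): Kaplan–Meier (forward and
  reverse, with a deaths-before-censorings tie convention), log-rank
  test, Weibull proportional-hazards regression (HR < 1 favours the
  panel-tested arm).
- **Partitioned IPCW estimation** (`panelcea.ipcw`): 3-year mean
  discounted costs and life-years per arm over monthly intervals,
  weighting each fully-accounted patient-interval by the inverse
  probability of remaining uncensored, 1/Ĝ(min(T, interval end)⁻), with
  Ĝ from the reverse Kaplan–Meier; ΔC and ΔE as treated-minus-control
  increments (equivalently, IPCW-weighted linear regression).
- **Bootstrap decision analysis** (`panelcea.cea`): resampling of matched
  pairs, incremental net monetary benefit INMB(λ) = λ·ΔE − ΔC at
  $50,000 and $100,000 per life-year gained, bias-corrected (BC)
  confidence intervals, the cost-effectiveness acceptability curve, the
  CE-plane quadrant decomposition, and the standard sensitivity grid
  (replacement matching, reduced test cost, societal perspective, 1-/2-
  year horizons, EGFR subgroups, SUR).
- **Synthetic cohorts** (`panelcea.synthetic`): because the linked
  administrative data such studies use are confidential, a generator
  emulates the setting — 2,172 patients, 43.2% treated, confounded
  assignment, Weibull survival with HR 0.932, 26–32% censoring, monthly
  costs with systemic-therapy dominance, an end-of-life spike and
  per-test costs of $1,200 vs $228 — together with a brute-force oracle
  (`true_estimands`) for the censoring-free truth.

See `docs/methods.md` for the full model descriptions, conventions and
limitations.

## Worked example

```python
import panelcea as pc

cohort = pc.generate_cohort(pc.default_config(n_patients=2172, seed=7))
match = pc.genetic_search(cohort, pc.MatchingConfig(
    population_size=40, max_generations=12, ks_boot_reps=150, seed=8))
bal = pc.balance_report(cohort, match)
grid = pc.build_grid(horizon_years=3, annual_discount_rate=0.015)
ce = pc.bootstrap_ce(cohort, match, grid=grid, B=1000, seed=9)
```

This run prints (via the fields of `match`, `bal` and `ce`):

```
matched 865/941 treated (91.9%)
max post-match SMD = 0.101, max variance ratio = 3.09
delta_C = $9,929 CAD  (95% BC CI 2,074, 17,603)
delta_E = -0.003 LY   (95% BC CI -0.100, 0.086)
INMB @ $50k/LYG = $-10,055 (CI -15,676, -4,229); P(cost-effective) = 0.0%
INMB @ $100k/LYG = $-10,181 (CI -16,731, -2,821); P(cost-effective) = 0.3%
quadrants: {'NE': 0.478, 'SE': 0.0, 'NW': 0.52, 'SW': 0.002}
```

Reading this: 91.9% of panel-tested patients found a control sharing their
exact-match stratum; after matching every standardized mean difference is
at (or just above) the 0.1 adequacy threshold, while the variance ratio of
one heavy-tailed covariate exceeds 2 — the balance table flags it, and the
methods note explains why matched variance ratios of lognormal covariates
are noisy across seeds.  The incremental life-year estimate from a single
cohort of this size is dominated by sampling noise (the generating hazard
ratio is only 0.932, and the BC interval for ΔE spans zero accordingly);
in this draw the panel-tested arm shows no survival gain, so the extra
~$9,900 of cost is not worthwhile at either threshold and most bootstrap
mass sits in the NE/NW quadrants.  Other seeds land on the favourable
side; the intervals are the honest summary.

The same stages are available from the shell:

```bash
panelcea simulate --seed 7 --n 2172 --out cohort.csv
panelcea match    --cohort cohort.csv --out pairs.csv
panelcea balance  --cohort cohort.csv --pairs pairs.csv --out balance.csv
panelcea estimate --cohort cohort.csv --pairs pairs.csv --out est.json
panelcea cea      --cohort cohort.csv --pairs pairs.csv -B 1000 --out-dir cea/
panelcea all      --seed 7 --out-dir run/        # full pipeline + report.md
```

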