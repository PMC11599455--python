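# Methods

`panelcea` implements a complete observational cost-effectiveness pipeline
for comparing multi-gene panel sequencing against single-gene EGFR testing
in advanced non-small-cell lung cancer, using patient-level administrative
data: covariate matching to address confounded test assignment, censoring-
robust estimation of 3-year mean costs and survival, and bootstrap decision
analysis.  Because the linked administrative data such an analysis runs on
are confidential, the package ships a synthetic-cohort generator that
reproduces the statistical structure of that setting together with a
brute-force oracle for the true estimands, so every stage of the pipeline
is testable end to end.

## The synthetic cohort

`synthetic.default_config()` encodes the emulated study conditions: 2172
patients with a 43.2% treated fraction, entering uniformly over a 852-day
accrual window with follow-up administratively truncated 1217 days after
the start of accrual and capped at three years per patient.

**Covariates.** Age ~ N(69, 10); binary sex (45% male); days since
diagnosis ~ lognormal(4.35, 1.2) (median ≈ 77 d with a long right tail);
number of cancer sites (69/22/9%); prior systemic-therapy lines (84/14/2%);
prior surgery (8.5%); residence in the Vancouver Coastal health authority
(20%); and last-month baseline healthcare cost ~ lognormal(7.9, 1.3)
(median ≈ $2,700).  Three covariates — prior therapy lines, prior surgery
and VCH residence — are flagged for exact matching, mirroring the applied
setting where the largest non-continuous imbalances are handled by
stratum matching.

**Assignment.** Treatment follows a logistic model whose linear predictor
uses the one-hot expanded covariates; the intercept is solved numerically
so the marginal treated fraction matches the target.  Skewed covariates
enter on the centred log scale (`<name>_log` coefficient keys).  This is a
deliberate modelling choice: confounding on the raw scale of a heavy-tailed
covariate pushes the treated tail outside the control support entirely, in
which case no matching method (ours or any other) can achieve balance
without replacement; log-scale confounding distorts the quantiles while
preserving overlap, which is the regime in which a matching study is
meaningful.

**Survival.** Weibull proportional hazards with shape 0.8 and control
scale 390 d (mean ≈ 442 d, median ≈ 246 d), treatment log-hazard
ln(0.932), and covariate effects on the hazard (age +0.02/yr, prior lines
+0.20/+0.35, prior surgery −0.25, centred log baseline cost +0.15).  The
covariate effects exist because confounding of the *estimand* requires
covariates that influence outcomes, not only assignment; without them
matching would be irrelevant to bias and the pipeline untestable.

**Censoring.** Administrative (entry-dependent potential follow-up) plus
exponential dropout at 0.12/year, together yielding ≈27% censoring overall
(≈29% treated, ≈26% control), inside the 26–32% band the emulated setting
exhibits.  Censoring is independent of survival and costs given entry,
which is the assumption the IPCW estimator needs; the generator makes it
true by construction.

**Costs.** Monthly payer costs are lognormal (μ=7.4, σ=0.9) with a
patient-level random effect coupled to the baseline-cost covariate;
patients on systemic therapy (uptake 55% treated / 50% control) add a flat
$4,000/month; a $15,000 terminal-care spike is spread over the last two
months before death — attached to the *death date*, so a patient censored
before death has part of the spike unobserved, inducing the positive
cost–censoring correlation that motivates the horizon and SUR sensitivity
analyses.  The per-test cost ($1,200 treated, $228 control) is charged in
month 1.  Out-of-pocket drug costs (lognormal, median ≈ $148/month) are
generated separately and only enter under the societal perspective.  Costs
accrue at month granularity (one month = 365.25/12 = 30.4375 days, fixing
the length of a "monthly interval"); the month containing the event is
prorated to the event day.  The lognormal forms are modelling conveniences
chosen for skewness, not estimates from any data source.

**Oracle.** `true_estimands` simulates ≥10⁵ patients per arm with
treatment forced and censoring disabled and accumulates discounted costs
and life-years on the same grid as the estimator.  It is the randomized
(marginal) estimand; the matched analysis targets a treated-like
population, so small differences are expected under covariate-dependent
hazards, and parameter-recovery tests therefore disable confounding.

**What the generator does not emulate.** Claim-level records (costs are
drawn directly at monthly granularity), turnaround times, competing risks,
time-varying treatment, and dependent censoring.  Tests passing on this
generator show the estimators are correct under independent censoring and
the stated structure; they cannot certify behaviour under informative
censoring or model misspecification in real data.

## Genetic matching

Treated patients are matched 1:1 to controls within exact-matching strata
by greedy nearest-neighbour search on a generalized weighted Mahalanobis
distance d(i,j) = sqrt((xᵢ−xⱼ)ᵀ L⁻ᵀ diag(w) L⁻¹ (xᵢ−xⱼ)), where L is the
Cholesky factor of the pooled pre-match covariance and w a positive
per-covariate weight vector.  Exact-match covariates are excluded from the
distance space (they are constant within strata).  The fitted propensity
score (logistic regression, probabilities clipped to [10⁻⁶, 1−10⁻⁶] with a
warning under near-separation) is appended as an additional distance
covariate by default and its standardized coefficients scale the jitter of
the initial weight population — both standard practice for genetic
matching; a flag disables the extra covariate.

A genetic algorithm evolves w to maximise post-match balance: the fitness
of a weight vector is the ascending-sorted vector of balance p-values —
bootstrapped Kolmogorov–Smirnov tests (pooled-resample null) for
continuous terms, paired t-tests on within-pair differences for binary
terms — over the covariates plus squared age and an age×sex interaction.
Vectors are compared lexically from the worst-balanced covariate: at the
first differing position the larger p-value wins, so the algorithm always
attacks the worst imbalance first.  Generations use tournament selection
(size 3), log-space blend crossover, multiplicative lognormal mutation
(per-gene probability 0.3, σ=0.35), elitism of one, and weight clipping to
[10⁻³, 10³]; search stops after `max_generations` (default 30) or 8
generations without lexical improvement.  Defaults: population 100,
`ks_boot_reps` 300.

Numerical conventions: greedy matching visits treated patients in a seeded
random permutation; distance ties are broken by a seeded random choice
among equidistant controls (not fractional weights); without replacement a
control is used at most once, with capped replacement at most k times
(k = 3 reproduces the replacement sensitivity analysis).  All random
streams inside a search run are fixed functions of the matching seed —
match order, tie-breaks and KS bootstrap resamples are common random
numbers across fitness evaluations, so the fitness surface is
deterministic within a run and the whole search is reproducible.  A
zero-variance binary term scores p = 1; a singular covariance gains a
10⁻⁸ ridge with a warning.

## Balance diagnostics

Absolute standardized mean differences divide by the pooled *pre-match*
SD (binary terms: sqrt(p̄(1−p̄)) of the pooled pre-match proportion), held
fixed after matching so pre/post values share a denominator; the pooling
convention for the applied analogue is not documented, and this choice
prioritises comparability.  Variance ratios are reported orientation-free
as max(r, 1/r), so the conventional <2 criterion reads the same whichever
arm is more variable.  Adequacy flags use SMD < 0.1 and VR < 2.  The
matched variance ratio of a heavy-tailed covariate is dominated by a
handful of extreme values and is noisy across seeds even when SMD and KS
diagnostics are good; the balance table reports all three so that no
single statistic is over-read.

## Survival models

The product-limit estimator (forward and reverse) is implemented
explicitly because the IPCW weights require two conventions that generic
implementations do not expose: deaths are processed before censorings at
tied times — a patient dying at t remains in the censoring risk set
through t — and the censoring survival function Ĝ must be evaluable as a
left limit Ĝ(t⁻).  Both follow from defining risk sets as {Xᵢ ≥ t}.  The
forward KM agrees with lifelines' to 10⁻¹⁰ on simulated data; Greenwood
variance, log(−log) median CIs and restricted means (3-year horizon, with
the standard large-sample variance) are provided.  The log-rank test is
lifelines'.  The Weibull PH fit wraps lifelines' AFT maximum-likelihood
fit and converts to hazard ratios via log HR = −shape·β_AFT with a
delta-method Wald CI using the full (β, log shape) covariance; HR < 1
favours the treated arm.  The default fit is treatment-only on the
matched sample.

## Partitioned IPCW estimation

The 3-year horizon is split into 36 monthly intervals; interval j carries
the discount factor (1+r)^(−start_j/365.25) with r = 0.015/year applied
identically to costs and life-years (discounting evaluated at interval
start; the timing convention is ours).  For each arm, Ĝ is the reverse KM
of that arm's matched patients (per-arm by default because censoring is
differential; a pooled option exists).

A patient-interval record enters the estimator only if follow-up fully
accounts for the interval: the patient dies under observation (at any
time — post-death intervals are retained as zero-accrual records, the
Bang–Tsiatis convention) or remains observed through the interval end.
The weight is the inverse probability of that completeness,
1/Ĝ(min(T, end_j)⁻): deaths carry their death-time weight, survivors carry
1/Ĝ(end_j⁻), and a patient censored alive inside an interval contributes
nothing from that interval on.  Under independent censoring each included
contribution then has exactly mean one, which makes the interval means —
computed as weighted (Hájek) means — unbiased even when censoring falls
strictly inside an interval.  The superficially natural alternative of
weighting everyone observed at the interval *start* by 1/Ĝ(start⁻) counts
truncated partial accruals as complete and is measurably biased downward
(≈ −6 Monte Carlo SEs over 200 simulated cohorts in our harness); the
completeness convention removes that bias while leaving every
zero-censoring identity intact (all weights 1, estimator equals the naive
mean to 10⁻¹⁰).

Arm means are Σⱼ d_j · weighted-interval-mean; increments are treated
minus control.  The equivalent formulation as per-interval weighted linear
regressions of accrual on the arm indicator is also implemented
(statsmodels WLS) and asserted equal to the weighted-means path; the
bootstrap uses the algebraically identical array path for speed.  An empty
risk set before the horizon truncates the horizon with a warning.  The
SUR-style joint estimator exploits that with identical regressors and
weights in both equations, feasible GLS coincides with equation-by-
equation WLS; it therefore returns the same point estimates plus the
cross-equation residual correlation, estimated over patients with complete
follow-up within the horizon.

## Bootstrap decision analysis

Uncertainty comes from resampling matched *pairs* with replacement
(B = 1000 by default), preserving the 1:1 structure and hence the
cost–effect correlation; the reverse KM, weights and increments are
recomputed inside every replicate.  Matching itself is not re-run inside
replicates — at these problem sizes a genetic search per replicate is
computationally disproportionate, and the resampling unit already reflects
the matched design; `run_sensitivity` re-runs matching only where the
scenario changes the matching rule (replacement).  Degenerate replicates
(undefined weights, empty subgroup arm) are redrawn, at most 5% of B.

INMB(λ) = λ·ΔE − ΔC; the CEAC evaluates P(INMB > 0) over draws on a
$0–$200,000 grid in $2,500 steps; quadrant proportions place boundary
draws on the positive side so counts always sum to B.  Confidence
intervals are bias-corrected (BC, without acceleration — matching the
stated method of the emulated analysis): z₀ = Φ⁻¹(#{draws < point}/B),
endpoints at the Φ(2z₀ ± z_{α/2}) percentiles; a point estimate outside
the draw range clamps z₀ with a warning, identical draws give a degenerate
interval.  The INMB interval is the BC interval of the per-draw INMBs,
never a recombination of the ΔC and ΔE intervals.

The sensitivity suite reproduces the standard scenario grid: capped(3)
replacement matching; treated test cost replaced by the single-gene cost
(month-1 adjustment of −$972); societal perspective (adds out-of-pocket
costs); 1- and 2-year horizons; EGFR-positive/negative subgroups — each
arm is filtered by the patient's *own* test result after matching (and
after pair resampling within each replicate), so subgroup arms are
generally unequal, as in the emulated analysis; subgroups under 30 pairs
are flagged, not dropped; and the SUR estimator.

## Problem sizes and reproducibility

All randomness flows from explicit seeds (numpy Generator); the pipeline
derives stage seeds from one master seed via SeedSequence, and a rerun
with the same configuration is bit-identical.  The test suite exercises
the estimators at deliberately moderate sizes — e.g. bias studies over 200
cohorts of n = 1,000, hazard-ratio recovery at n = 10,000, the balance
study at n = 2,000 with a population of 50 for 15 generations, pipeline
determinism at n = 400 — and `scripts/acceptance.py` runs the full default
cohort (n = 2,172) with a population of 40 for 12 generations and
B = 1,000.

## Known limitations

- Greedy nearest-neighbour matching is order-dependent; optimal
  (network-flow) matching, calipers and 1:k designs are out of scope.
- With ~43% treated and strong confounding, some exact strata exhaust
  their controls; unmatched treated patients (typically 8–9%) are dropped
  from the matched analysis, as in any without-replacement design.
- The matched variance ratio of lognormal covariates is tail-dominated
  and seed-noisy; single-run VR values near 2 should be read alongside
  the KS statistic.
- A single cohort at n ≈ 2,000 cannot distinguish a hazard ratio of 0.932
  from 1 (the Wald CI spans ≈ ±0.11 on the log scale); point estimates of
  ΔE from one simulated cohort routinely change sign across seeds, and
  the bootstrap intervals say so.
- The IPCW estimator assumes censoring independent of costs and survival
  within arms; it is not doubly robust and no covariate-adjusted
  weighting is provided.
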