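# Methods

`goutcea` implements a one-year, daily-cycle, patient-level Markov model of
newly diagnosed gout, built to compare treatment strategies that combine a
urate-lowering therapy (ULT: allopurinol 200/300 mg, febuxostat 80 mg, or
none) with an anti-inflammatory drug for acute flares (naproxen,
colchicine, prednisone, or anakinra), from a societal costing perspective.

## Model structure

A patient enters the model on day 0, by default in the middle of a gout
flare (they present with an attack and initiate ULT at diagnosis). At
entry the patient is assigned once, with the ULT-specific probability
`p_target`, to the *on-target* branch (serum urate < 0.36 mmol/L) or the
*off-target* branch; no switching of branch, ULT or flare drug is allowed
for the rest of the year. Patients with no ULT never reach the target.

On every flare-free day a new flare begins with a branch-specific daily
probability (on target with ULT 0.000716; off target with ULT 0.001222;
off target without ULT 0.001637 — constant-hazard conversions of annual
probabilities taken from an earlier gout cost-effectiveness model, so that
`p_daily = 1 − (1 − p_annual)^(1/365)`). A flare lasts exactly seven days.
During a flare the patient occupies one of four ordinal pain states
(no / mild / moderate / severe pain) and transitions daily according to a
row-stochastic 4×4 matrix specific to the flare drug; onset is severe pain
by default (gout attacks present with rapid-onset severe pain), and a
configurable onset distribution is available. Flares cannot overlap; a
flare that would overrun the horizon is truncated at day 364. The day
after a flare ends a new one may begin.

### Accrual

Each day contributes discounted cost and utility:

* **Utility.** The state's utility weight (no flare accrues the no-pain
  weight 0.86; in-flare weights 0.86/0.77/0.70/0.61), minus a constant
  disutility while off target, divided by 365 and discounted at
  1.5 %/year. The off-target disutility (default 0.05 QALY/year) has no
  published value; it is a calibrated package default chosen so the
  QALY separation between ULT arms matches the magnitudes reported for
  the original model (≈0.024 allopurinol vs no ULT, ≈0.012 febuxostat vs
  allopurinol), and it is exposed in the configuration.
* **Cost.** ULT drug cost every day (allopurinol €0.13, febuxostat
  €1.03/day), flare drug cost on each of the seven flare days (naproxen
  €0.21, colchicine €0.61, prednisone €0.26, anakinra €33.40/day; the
  dosing window is configurable), and the state's daily "other" cost
  (healthcare plus lost productivity: €19.95/32.39/58.08/134.32 by pain
  state), discounted at 4 %/year.

Days without a flare accrue the no-pain utility and, by default, the
no-pain daily other cost. Both conventions are assumptions: the original
report distinguishes the no-flare state structurally but prints utilities
and costs only for the four in-flare pain states. The no-flare daily cost
is configurable (`no_flare_daily_cost`); because it multiplies ~358 days,
absolute cost levels depend on it strongly — which is exactly why absolute
published totals are not reproducible (see *Validation*, below).

Discounting uses daily factors `(1+r)^(−day/365)` with day 0 undiscounted;
no half-cycle correction (one-day cycles make it immaterial).

## Evidence synthesis

**Flare-drug transition matrices.** From patient-level trial panels
(daily 4-level pain scores over up to seven days), consecutive-day
transitions are counted, pooled over patients, and combined with a
noninformative Dirichlet prior of 0.5 per cell so sparsity never leaves
empty cells. Deterministic analyses use posterior means; the PSA samples
each row from its Dirichlet posterior. When two trials inform one drug,
posterior-mean probabilities are pooled entry-wise by inverse variance
(Dirichlet-mean variances `m(1−m)/(n₀+1)` as binomial-style standard
errors) and rows renormalized; pooling raw counts first is available
behind `method="counts"`. Panels observed at sub-daily granularity (e.g. a
90-hour trial) contribute only the daily transitions actually observed.

**ULT efficacy.** Arm summaries (responders/n achieving the serum-urate
target) are meta-analyzed by Bucher's adjusted indirect comparison with
febuxostat 40 mg as the common reference: within-trial log-odds contrasts
(Woolf standard errors, 0.5 continuity correction on boundary arms) are
pooled by inverse variance across trials and back-transformed to an
absolute probability anchored at the pooled reference-arm rate, with a
delta-method standard error. The correlation between the pooled reference
rate and the contrasts (they share arms) is ignored, as is standard for
this estimator. No-ULT is fixed at exactly (0, 0): no placebo patient
reached the target in the source trials.

Because the underlying patient-level data are not redistributable, the
package bundles *synthetic stand-in* transition matrices for all four
flare drugs (`data/synthetic_flare_matrices.yaml`), hand-constructed once
on clinical grounds: substantial relief within 24–48 h, most patients at
no/mild pain by day 3, near-complete resolution within a week; anakinra
slightly faster, colchicine/prednisone slightly slower than naproxen. A
user who obtains the published naproxen matrix can drop it into a fixtures
directory (`s1_naproxen_matrix.csv`); the run manifest records per-drug
provenance (`published` vs `synthetic`).

## Probabilistic sensitivity analysis

Two-level design, 2,000 outer × 200 inner by default (both configurable):
each outer replication draws one parameter set, shared by all strategies;
the inner cohort of patients is simulated per strategy under common random
numbers (one pre-drawn block of uniforms per outer replication drives
branch assignment, flare onsets and pain transitions for every strategy),
so between-strategy contrasts reflect parameters, not simulation noise.

Per-parameter PSA distributions follow the published input table:

* `p_target`: betas from the printed mean/sd (method of moments).
* Daily flare probabilities: the printed betas (μ ≈ 0.998–0.999,
  σ = 0.002) evidently describe the *complement* of the small daily
  probability. We sample `q ~ Beta` with mean rescaled so `1 − E[q]`
  equals the printed point estimate and the printed σ, and set
  `p = 1 − q`. Note σ = 0.002 exceeds the point values (~0.001), so
  drawn hazards are strongly right-skewed; occasional draws are an order
  of magnitude above the point estimate. This is a faithful reading of
  the printed table, and it makes 200-draw PSA means noticeably noisy.
* Utilities: the printed beta *shapes* unmodified. Their means (e.g.
  0.8415 for no pain) differ from the printed point estimates (0.86);
  both are printed, so deterministic runs use points and the PSA uses the
  shapes — we do not silently rescale.
* Daily other costs: productivity (exponential, rate λ) plus healthcare
  (gamma, shape/scale) components sampled from the printed parameters;
  since the printed component means do not sum to the printed daily
  totals (units unstated), the sampled total is rescaled by a state
  constant so its mean equals the printed point estimate — the printed
  distributions supply relative uncertainty only.
* Drug prices and the no-ULT attainment probability are fixed.

Everything is reproducible from one master seed (`numpy` `SeedSequence`
spawning per-draw parameter and simulation streams).

## Economic outputs

Strategies are compared by mean discounted cost and QALYs. The
incremental analysis sorts by cost, removes strictly dominated strategies
(another strategy no costlier and no less effective), removes extended
dominance by enforcing increasing ICERs along the efficiency frontier,
and reports ICERs between adjacent frontier members; dominated rows report
increments against the nearest cheaper frontier member (the layout used in
the published tables), and a pairwise comparison table against any named
comparator is available. Cost-effectiveness acceptability curves use the
multi-way net-monetary-benefit argmax (`NMB = λ·QALY − cost`) over a WTP
grid of €0–80,000/QALY in €1,000 steps (the Dutch threshold range is
€10,000–80,000 by disease burden); exact NMB ties split probability mass
equally, so curves sum to one at every grid point.

## Exact oracle

`expected_outcomes_exact` propagates the exact probability distribution
over the 29-point state space {no flare} ∪ (pain state × flare day) day by
day within each serum-urate branch, mixes branches by `p_target`, and
returns exact expected discounted cost, QALY and flare count. It is
validated against exhaustive enumeration on toy horizons and serves as the
oracle for microsimulation bias checks (agreement within 3 Monte-Carlo
standard errors at n = 200,000), hazard-monotonicity and the scenario
contracts. One nuance: a hazard multiplier `m` scales the *hazard*
exactly, but expected flares scale slightly less than `m` because
flare-day occupancy reduces exposure (`F(m) ≈ 365mh/(1 + 7mh)`; ratio 4.86
rather than 5 at m = 5 for the no-ULT hazard). Tests assert the
occupancy-corrected value.

## What the synthetic generators emulate — and what passing tests show

`generate_flare_panel`, `generate_ult_trials` and
`generate_cost_observations` produce trial panels, arm summaries and cost
observations from known ground truth, in the same CSV schemas the
estimation layer reads. They emulate structure (7-day daily panels,
shared-reference trial networks, two-component cost observations with
injected ×50 outliers flagged in a sidecar), not clinical realism: no
covariates, dropout, missingness or within-patient correlation beyond the
Markov chain. Recovery tests therefore demonstrate estimator correctness,
not robustness to real-data pathologies.

Two measured caveats are documented rather than hidden:

* At the published heavy-tailed cost shapes (gamma α ≈ 0.3), genuine
  observations beyond 3 SD occur at ~1 % rates and injected ×50 outliers
  inflate the stratum SD enough to mask themselves (≈40 % survive a single
  pass at n = 1,000). Screening-behaviour tests therefore use a
  light-tailed parameter set; component-recovery tests keep the published
  shapes.
* The transition-recovery bound (max entry error < 0.02 at n = 5,000, 7
  days, severe onset) sits at ≈2.5σ for the least-visited row; roughly one
  seed in eight exceeds it. The committed test seeds pass.

## Validation against the published results

Exact reproduction of the published mean costs/QALYs is not possible from
public information: the no-flare utility/cost conventions and the
off-target disutility behind them are unreported, and the per-drug
transition matrices are stand-ins. The package therefore validates:

1. **Worked-example arithmetic** — feeding the published PSA summary means
   into the incremental analysis reproduces the published increments and
   ICERs exactly (allopurinol vs no ULT €1,381.27/QALY; febuxostat vs
   allopurinol €25,173.06/QALY; the published dominance labels for
   colchicine and prednisone under every ULT).
2. **Oracle equivalence** — the microsimulation is an unbiased estimator
   of the exact expectation for all 12 base-case strategies.
3. **Qualitative reproduction** — a reduced PSA (200 × 200) with the
   bundled inputs reproduces the published orderings: QALY and cost both
   increase from no ULT to allopurinol to febuxostat, and anakinra's
   pairwise ICER against naproxen exceeds €80,000/QALY (here ≈€3M) under
   every ULT.

One fragility is worth stating plainly: with these inputs the discounted
allopurinol drug cost (≈€47/year) is almost exactly offset by its
avoided-flare savings, so the *cost* gap between allopurinol and no ULT is
only ≈€5 at point estimates (≈€30 at the committed PSA seed). Its sign at
200 outer draws varies with the seed because the hazard and cost draws are
heavy-tailed. The QALY orderings and every flare-drug conclusion are
robust across seeds.

## Problem sizes and defaults

| Quantity | Default | Notes |
| --- | --- | --- |
| Horizon | 365 days | one-day cycles |
| Flare duration | 7 days | fixed episode length |
| PSA | 2,000 × 200 | reduced to 200 × 200 in tests/acceptance |
| Oracle-equivalence cohorts | 200,000 | 100,000 in the acceptance script |
| WTP grid | €0–80,000 step €1,000 | configurable |
| Off-target disutility | 0.05 QALY/yr | calibrated, unsourced; configurable |
| No-flare daily cost | no-pain cost (€19.95) | assumption; configurable |

## Known limitations

No mortality, adverse events, ULT titration or dose sequences,
prophylaxis, or horizons beyond one year (all outside the model's scope);
SF-6D valuation is consumed as numbers, not re-derived; unit costs are
taken as printed, with no currency-year adjustment.
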