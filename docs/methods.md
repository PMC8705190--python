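# Methods

## Study design being modelled

The analysis targets a two-arm programme evaluation in which insured
adults with chronic low back pain were randomised before consent (Zelen's
design) and then self-selected into a 12-month rehabilitation programme of
device-supported exercise plus behavioural coaching, or remained in usual
care. Outcomes come from two linked sources: questionnaire instruments at
baseline and 24 months (GCPS grade, STarT-Back, EQ-5D utility derived
upstream from SF-12, six-month-recall sick days) and quarterly claims
costs over a four-year window centred on each participant's individual
index date (quarter 0 = first post-index quarter). Costs are split into
total direct medical costs and back-pain-specific costs (ICD-10 M40–M54),
the latter partitioned into inpatient and outpatient components.

Self-selection makes the arms non-exchangeable, so the causal contrast is
estimated with a propensity-score-matched difference-in-differences
(PSM-DiD) design: matching restores baseline comparability, the DiD
removes shared secular trends, and the remaining interaction is the
average treatment effect on the treated (ATT).

## Pipeline stages and their conventions

**Exclusion cascade.** Four ordered, configurable rules: participants
without invoices in each of the four observation years (deductible-induced
gaps make their cost series uninterpretable), SUTVA violations (crossover
enrolment), deductible-only tariffs, and participants who never started
the exercise component (per-protocol analyses only). The cascade is
order-sensitive but count-conserving; an audit row per step records
overall and per-arm counts.

**Truncation.** DiD is sensitive to high-leverage observations, so
participants whose undiscounted two-year pre-index back-pain-specific cost
sum is *at least* €14,000 (inclusive bound) are removed after matching
eligibility and before estimation. The sum is undiscounted because the
baseline period is the reference period.

**Period aggregation.** The quarterly panel is collapsed to one baseline
value (sum of quarters −8…−1, undiscounted) and one follow-up value per
participant (year 1 = quarters 0–3 and year 2 = quarters 4–7, each
discounted at (1+r)⁻ʸ). Collapsing removes quarterly serial correlation
that would otherwise bias the DiD standard errors. The extended window
−16…−1 is used only by the parallel-trend check.

**Propensity model and matching.** Logistic regression of treatment on
sex, Charlson comorbidity class (scored 0–3), GCPS grade (1–4),
STarT-Back risk (1–3), age, pre-index total costs and pre-index sick days;
continuous covariates are standardised so coefficients are comparable.
Perfect separation and rank deficiency are diagnosed explicitly rather
than silently regularised. Matching is greedy 1:1 nearest neighbour
without replacement, processing treated units in descending score order,
with ties broken toward the smaller control id so results are invariant to
input order. The caliper defaults to 0.1 on the probability scale — the
most literal reading of "a caliper of 0.1" — with a `logit_sd` scale
(caliper × pooled SD of the logit scores) available, since that is the
other common convention. Optimal (Hungarian) matching is deliberately out
of scope; nearest-neighbour is the documented design.

**Effect estimation.** Cost outcomes: OLS on the 2-rows-per-participant
long table with a period × treatment interaction; the interaction equals
the four-cell-mean arithmetic identically, and standard errors are
cluster-robust by participant (model-based SEs available by flag — the
original estimator is unstated, and cluster-robust is the conservative
default for repeated observations). Questionnaire outcomes: one-sided
ANCOVA (follow-up on baseline + arm). The favourable direction is explicit
per outcome — fewer sick days, higher EQ-5D — because "one-sided" is
meaningless without it; the two-sided p is always reported alongside.
With zero baseline variance the ANCOVA degenerates gracefully to a
two-sample comparison with a logged notice.

**Economics.** Costs and effects are discounted by the same full-horizon
factor (1+r)⁻² (Keeler–Cretin consistency): QALY gain = ΔEQ-5D × 2 ×
(1+r)⁻², ICER = (ATT + €1,500)/QALY gain. This full-horizon convention is
the one that reproduces all published ratios from their printed inputs.
The €100×2 exercise bonus is excluded from the programme cost by default
(it was optional and rarely used) but can be added via `extra_cost`.
Dominance is the CE-plane quadrant of (QALY gain, incremental cost); a
zero EQ-5D difference leaves the ratio undefined and flags the result.

**Bootstrap.** Participants are resampled with replacement independently
within arms (matched pairs define the analysis set but are not treated as
the resampling unit by default; a paired mode exists for comparison). Per
replicate the incremental cost is the cell-mean DiD plus programme cost —
exactly the regression coefficient, so no refit is needed — and the QALY
gain is the change-score EQ-5D contrast, scaled by horizon and discount
factor. The CEAC reports P(net monetary benefit > 0) on a €0–50,000 grid
(€250 steps, always containing the €20,000 and €30,000 anchors);
confidence intervals use equal-tailed percentiles with linear
interpolation between order statistics, so results are bit-reproducible
given the seed.

**Scenarios.** `per_protocol` applies all four exclusion rules, `itt` skips
the non-exercising rule, `original` applies only the no-billing rule,
skips matching and truncation, and so mirrors an analysis without data
preparation. Subgroups: minor (GCPS I–II) vs major (III–IV) impairment;
the "profiteer" subset (lower STarT-Back raw score at follow-up and no
GCPS regression, with GCPS ordered I<II<III<IV) split at the pooled median
of pre-index total costs within the 0.1–0.9 quantile band. The quantile
position of the rank-i participant among n is (i−0.5)/n, the low band is
closed, the high band half-open above the median, and ties break by
participant id. The split is pooled across arms (a per-arm variant would
change group sizes; the pooled reading matches a single cost distribution
being banded).

## Synthetic-cohort generator

The generator is first-class, tested code: it produces exactly the
structure the estimators assume, with known truth. Covariate marginals
default to the published cohort description (age ≈ N(55.2, 8²) clipped to
18+, 35 % female, GCPS ≈ (37, 17, 23, 23) %, STarT-Back ≈ (55, 33, 12) %,
Charlson classes ≈ (50, 37, 10.5, 2.5) %). Treatment is drawn from a
logistic selection model on the standardised matching covariates;
`selection_strength` (default 0.3 log-odds per standardised unit, chosen
to mimic the modest published baseline imbalance) controls how strongly
sicker, older participants self-select into the programme.

Quarterly costs are gamma distributed (shape 1.2 for back-pain costs —
strongly right-skewed, as claims costs are) around GCPS-graded means
calibrated to the published two-year period sums: back-pain-specific
quarterly means (290, 360, 440, 500) € for grades I–IV reproduce baseline
sums near €2.5k (minor) and €3.7k (major), and the non-back-pain
components (1450–1950 €/quarter) bring total two-year costs near €16k.
A common €5/quarter linear drift keeps arm-level pre-trends parallel by
construction; `trend_gcps_gradient` (default 0) optionally ties the drift
to GCPS grade so that self-selection induces genuinely diverging arm
trends — the confounding that matching is supposed to remove — and
`generate_violated_trend_cohort` adds an explicit arm-specific pre-index
slope divergence as a negative control. A 6 % outlier fraction has its
pre-index back-pain cost scale inflated sixfold, which places their
two-year sums beyond the €14,000 truncation threshold. Exclusion-flag
rates (2 % missing billing years, 1 % SUTVA, 6.5 % deductible-only, 8 %
non-exercising) approximate the published preparation cascade.

Treatment effects are injected additively for treated participants only:
back-pain cost changes spread evenly over the 8 follow-up quarters (and
therefore also visible in total costs), EQ-5D and sick-day shifts on top
of a shared secular drift. Defaults are the published subgroup effects
(−€571/−€1,824 back-pain costs, +0.039/+0.047 EQ-5D, −9.5/−27.2 sick days
for minor/major impairment), so recovery experiments target realistic
magnitudes. Every injected quantity is returned in a truth ledger.

One root seed drives a splittable `SeedSequence`; participant *i* always
uses child stream *i*, so enlarging a cohort extends it without
reshuffling existing participants.

What the generator does **not** emulate: billing-code structure and
co-diagnosis ambiguity on invoices, calendar-time seasonality and
inflation (costs are generated in reference-year euros; the CPI hook is
exercised with explicit tables), within-participant serial correlation of
quarterly costs beyond the deterministic trend, and informative dropout.
Passing tests therefore demonstrate correctness of the estimators under
the stated assumptions, not robustness to those real-data features.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 150–500 per arm with 20–100 seeds
per experiment, and bootstrap sizes of 200–5,000 — sizes at which the
checked properties (parameter recovery within 2 bootstrap SEs in ≥90 % of
runs, ≥90 % power against a €50/quarter trend divergence, SMD reduction
for all covariates imbalanced beyond 0.1) hold with comfortable margin.
Logistic estimation uses Newton iterations to a 1e−8 log-likelihood
tolerance (max 100). Matching and quantile ties break by participant id.
The four-cell DiD identity is asserted to 1e−9 relative precision.
Degenerate inputs (zero baseline variance, zero EQ-5D difference,
all-equal costs, empty arms) are handled explicitly and logged or raised
rather than silently propagated.

## Known limitations

* The matching defaults (no replacement, greedy order, probability-scale
  caliper) are documented choices; the original analysis did not state its
  variant, and different choices move results within sampling noise.
* The bootstrap QALY gain uses the change-score contrast rather than the
  ANCOVA coefficient; the two coincide under baseline balance (which
  matching enforces) but can differ slightly in unmatched scenarios.
* Sick days are not monetised, mirroring the payer perspective.
* No lifetime-horizon extrapolation: the two-year window is the data's
  horizon.
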