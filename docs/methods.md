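# Methods

## Setting and model

The package targets cohorts of hospital deliveries with a binary in-hospital
death outcome whose prevalence is far below 1%, a handful of categorical
covariates per patient, and a hospital-type stratum label.  The statistical
object is the class association rule `A → death`: `A` is a conjunction of
`variable=level` items, at most one item per variable, including explicitly
negative levels (`vaginal_bleeding=no`), because protective-looking
conditions are informative parts of published risk patterns.

For a rule with counts `a = #(A ∧ death)`, `m = #A`, `D = #death`, `N` total:

| measure | definition | role |
|---|---|---|
| support | `a/N` | classical Apriori frequency |
| local support | `a/D = P(A \| death)` | frequency within the death class |
| confidence | `a/m = P(death \| A)` | rule precision |
| relative risk | `(a/m) / ((D−a)/(N−m))` | effect size vs. non-matching patients |

With a rare outcome, thresholding on support is useless (every interesting
rule is "infrequent"), so mining thresholds on **local support**, which is
anti-monotone under antecedent growth — each added item can only shrink
`a` — and therefore supports level-wise Apriori pruning exactly like support
does.  Plain support is recoverable as `support = local_support · D/N`.
Relative risk is computed against patients *outside* the pattern; it is
`+inf` when every death lies inside the pattern, and undefined when the
pattern matches the whole cohort (`m = N`); the miner never emits such
patterns (a constant column is equivalent to the empty antecedent).

## Mining

`mine_risk_rules` runs level-wise: size-k candidates are lexicographic
prefix joins of frequent (k−1)-patterns over a fixed (variable, level) item
order, with joins repeating a variable skipped and every (k−1)-subset
required to be frequent.  Frequency counting runs on boolean masks restricted
to the death rows (a few hundred entries), so each candidate costs one
vectorised AND; `m` is counted on the full table only for candidates that
pass the local-support floor.  Confidence is an emission filter, never a
pruning criterion, and rules with RR ≤ 1 are still emitted — risk-direction
filtering is the selection stage's job, which keeps the stages orthogonal and
independently testable.  `brute_force_rules` enumerates every pattern up to
the length cap (guarded at 2^20 candidates) and is the oracle the miner is
tested against; the two must agree exactly, rule for rule and count for
count.

`max_len` counts antecedent items only.  A `max_len` of 0 is allowed and
yields the empty rule set.

## Pruning and validation

The non-redundant set keeps rule R iff no mined rule with a *strictly
smaller* antecedent has at least R's relative risk.  This is the
optimal-rule-set notion of redundancy: a specialization must buy extra
relative risk or it is noise around its generalization.  The filter is
idempotent, order-independent, and never removes a size-1 rule (the empty
pattern is excluded from rule sets by construction).  No multiple-testing
correction is applied across rules; the validation stage is the error
control, and this is a documented limitation.

Validation recomputes every surviving rule on the held-out validation third
and retains it only if (i) local support and (ii) confidence still clear the
mining thresholds there, and (iii) the 95% log-Wald RR interval lies strictly
above 1.  Retained rules carry their validation stats.  The RR interval is
the Katz log-scale Wald interval

    exp( ln RR ± z · sqrt(1/a − 1/m + 1/(D−a) − 1/(N−m)) ),

chosen because it is the standard closed form matching the Wald style of the
binomial Se/Sp intervals; its empirical coverage at the sample sizes used
here is 93–97% (checked by simulation in the test suite).  Any zero cell
makes the interval undefined and the rule is dropped with a reason rather
than patched by continuity corrections.

## Classifier, grid, and selection

The classifier is a plain union: predict death iff any retained pattern
matches.  No scores, weights, or stacking — the clinical use case is a
checklist.  Union classifiers are monotone: adding a rule can only raise
sensitivity and lower specificity, which the tests assert.

The training grid is (minimum local support) × (minimum confidence) ×
(maximum length) = {9%, 10%, 15%} × {2.1%, 2.8%, 3.5%} × {3, 4}, 18 points.
Each point is mined/pruned/validated and scored on the validation split; a
failing point (e.g. no deaths in a degenerate split) is flagged and skipped,
not fatal.  Selection maximizes Youden's J = Se + Sp − 1 on the validation
split.  "Optimal according to sensitivity and specificity, with
misclassification if necessary" admits several scalarizations; Youden's J is
the standard one consistent with picking a ROC corner, and ties are broken by
lower misclassification rate, then fewer rules, then grid order, so selection
is fully deterministic.  The test split is evaluated exactly once, for the
selected point only; the pipeline driver asserts this ordering.

Sensitivity and specificity carry Wald binomial intervals
`p ± z·sqrt(p(1−p)/n)` truncated to [0, 1].  On the published worked example
(164, 35, 5454, 24186) this reproduces Se 82.41% [77.12%, 87.70%] and the Sp
lower bound 81.16% exactly; the printed Sp upper bound (82.02%) differs from
the Wald value (82.04%) by 0.02 points and is documented rather than
reverse-engineered.

## Cohort model

Raw numeric fields are discretised at load time by codebook derivation
rules — age at 35 years, parity at 5, antenatal visits 0 / 1–3 / ≥4 — with
cut points belonging to the upper level (age 35 → "≥35", 4 visits → "≥4").
Missing raw values are rejected by default; a per-variable codebook flag maps
them to an explicit `missing` level that is excluded from the minable item
universe, because silent imputation would distort pattern counts.  The loader
exposes an optional exclusion filter over flag columns (death before
delivery, transfer out) and applies none by default.

The three-way split is simple random (unstratified — whether the original
analysis stratified by hospital or outcome is not stated, so the simplest
reading is implemented), sizes differing by at most one with earlier parts
taking the extras: 89,518 records split 29,840 / 29,839 / 29,839.  Records
keep their cohort order inside each part; nothing in the package sorts
records implicitly.

## Synthetic cohorts

`default_config()` emulates the shape of a two-country referral-hospital
cohort: six strata (capital / regional / district × two countries) with
proportions 15606 : 22617 : 8629 : 24118 : 7678 : 10870 over 89,518 and
baseline mortality 0.29 / 1.20 / 0.84 / 0.10 / 0.79 / 1.10 % (the capital
rate printed to one decimal is taken at face value), overall ≈ 0.69%.
Covariates are the fourteen predictor variables of the emulated analysis
(mode of delivery split into intra-partum and emergency ante-partum
indicators) plus six fillers, with realistic prevalences; referral and
cesarean rates vary by stratum (referral 15.6–37.8%, cohort totals ≈ 24.4%
referred, ≈ 18.9% cesarean, split 70/30 between intra-partum and emergency
ante-partum sections).

Planted effects act multiplicatively on the **odds** scale:
`odds(p) = odds(p0) · Π θ_j` over matching patterns, which keeps
probabilities in (0,1) without clipping; at sub-1% baselines θ is numerically
close to the marginal RR, but all recovery tests compare against the
Monte-Carlo oracle (`empirical_pattern_stats`, which simulates a fresh cohort
and returns the pattern's RR with a delta-method SE) rather than against θ,
because overlapping patterns and stratum mixing shift the achievable RR.
Covariates are independent by default; optional odds-scale couplings between
a source item and a binary target variable exist so that redundancy pruning
can be exercised on correlated items.  One `numpy` generator stream is
consumed in a fixed order (stratum → covariates in codebook order → outcome),
so appending a variable does not perturb earlier columns, and regeneration
from a config (including YAML round-trip) is bit-exact.

What the generator does **not** emulate: referral-network dynamics, temporal
or seasonal structure, correlated measurement error between hospitals, and
repeated deliveries per woman.  Tests passing on these cohorts show the
pipeline recovers known planted structure under realistic marginals and
rarity — not that it would reproduce any specific real-data rule set.

## The recovery experiment

`recovery_scenario()` is a designed experiment for end-to-end parameter
recovery at N = 90,000 over the six default strata and baseline rates, with
three two-item patterns planted at odds multipliers 30, 20, 10.  The design
constraints, solved analytically before freezing the numbers:

- every planted pattern must clear the *whole* grid on every split — so each
  pattern is sized to contribute ≈ 89 deaths per 30,000-record split
  (≈ 20% local support against the top 15% threshold, a ≥ 2.5-SE margin),
  giving joint prevalences 1.8% / 2.7% / 5.0%;
- single-item generalizations must not ride in and bloat the classifier — so
  each pattern pairs a *common* item (prevalence 0.75, single-item confidence
  ≈ 1.7% including cross-pattern contributions, below the 2.1% grid floor)
  with a *rare* item (prevalence 0.024 / 0.036 / 0.067) whose unavoidable
  single-item rule adds only ≈ 3% footprint and carries an RR diluted far
  enough below its pattern's that dominance pruning keeps the pattern.

Under these conditions the selected classifier's validated rules contain all
three planted patterns and its test-split Se/Sp sit within ≈ 3 percentage
points of the oracle classifier built from the true patterns (checked at
fixed seeds in `tests/test_acceptance.py` with a 5-point band).  The
prevalence overrides live only inside `recovery_scenario()`.

## Numerical and reporting conventions

- Counts are exact integers from full scans; no sampling anywhere.
- Ties in item ordering are broken lexicographically by (variable, level);
  rule sets are emitted sorted by (length, items), so results are independent
  of enumeration order.
- Rule-tree construction orders items within an antecedent by descending
  frequency across the rule set (ties lexicographic) before prefix-merging;
  duplicate antecedents merge with a warning.  A rule whose antecedent is a
  prefix of another's terminates at an internal node, so rule terminals (RR
  annotated), not graph leaves, are the unit of accounting.
- Report tables round percentages half-up to two decimals; JSON artifacts
  keep full precision.
- Problem sizes in the test suite and acceptance script (50 random cohorts of
  ≤ 500 records for oracle equivalence, 1,000 simulated tables for CI
  coverage, one 90,000-record recovery run) were chosen as the smallest sizes
  at which the corresponding statistical claims are sharp.

## Known limitations

- The exact pruning and validation criteria of the original analysis are
  published only in a separate methods paper; the RR-dominance and
  revalidation criteria here are a faithful reconstruction of their described
  effect and are configurable (`SelectionParams`) so alternatives can be
  swapped in.
- No multiplicity control across mined rules beyond out-of-sample validation.
- Simple random splitting; no stratified or repeated splits.
- The union classifier has no notion of rule cost or per-rule calibration.
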