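# Methods

## Data model

A patient record holds demographics (birthdate, sex), the treatment method,
the PJI manifestation date, a date-sorted sequence of at most 10 priced
surgical interventions, the PJI status at the last observation, an optional
death date, an explicit censoring date, and optional per-interval
EQ-5D-derived QALY increments (one per interval ending at each operation).
Interventions belong to a fixed 15-type taxonomy partitioned into three
groups of five — unrelated to PJI, compatible with a first PJI episode or a
relapse, and relapse-only — with exactly one type (endoprosthesis
installation + spacer removal) marking the second stage of two-stage
treatment. Label matching is whitespace- and case-insensitive because
archival data entry is noisy; dates are ISO 8601.

Eight treatment methods are modeled: three retrospective-cohort methods
(revision with prosthesis preservation, two-stage revision with a >2-month
interval, resection arthroplasty) and five prospective ones (two-stage at
2–3 weeks and at 6–8 weeks, one-stage, and the two partial-revision
variants). The historical one-stage retrospective group (3 patients) exists
in the demographic grid and in generated data — it is needed for the
cohort's bookkeeping totals (600 patients overall, 434 retrospective) — but
is excluded from every analysis: model fitting selects records whose cohort
tag matches the method's study cohort, which that group's records never do.

## Decision tree

Per method, patient courses are reduced to label sequences (operations
within the horizon, default 24 months after manifestation) terminated by an
outcome: `Death` if the patient died with PJI present, `Failure` if alive
with PJI at censoring, `Success` if PJI-free at the last observation. A
death without PJI counts as `Success` (the treatment eliminated the
infection); this case is otherwise unspecified by the outcome definitions,
and `died_without_pji` exposes the flag so the convention is auditable.

The tree is built by recursive prefix grouping: each node's children are the
distinct next operations among records sharing the node's prefix, plus
outcome leaves where sequences end; edge probabilities are occurrence
ratios, so outgoing probabilities sum to 1 at every inner node and a node's
support equals the sum of its children's supports. Children are ordered
lexicographically for deterministic serialization. Edge increments: cost is
the mean recorded cost of the child operation over supporting records;
utility is the mean recorded QALY increment over the preceding interval,
falling back to configured per-category defaults (0.3 QALY for non-PJI
intervals, 0.1 for PJI/relapse intervals) and per-outcome defaults for the
terminal interval (Success 1.7, Failure 0.7, Death 0 — roughly the
respective state utilities sustained over the remaining horizon). Expected
impact is the probability-weighted path sum `Σ pᵢ·cᵢ`; its interval
substitutes bootstrapped lower/upper edge probabilities into the same sum
(the bounds are not renormalized, matching the interval definition used
with the point formula). How branch probabilities are estimated is a
plug-in choice; occurrence ratios with subsample-bootstrap intervals are
the default.

## Markov model

Five generalized monthly states: `PJI` (waiting for PJI-related surgery),
`SECOND_STAGE` (no PJI, spacer in place), `NON_PJI_OP`, `OBSERVATION`,
absorbing `DEATH`. First episodes and relapses share one `PJI` state.
Months are fixed 30-day bins anchored at the manifestation date
(patient-anchored and deterministic, rather than calendar months).

Discretization rule: a month containing operations takes the *waiting*
state of its last operation (a PJI-category operation means the patient was
in `PJI` that month; the second-stage exchange means `SECOND_STAGE`; an
unrelated operation means `NON_PJI_OP`) — when several events fall in one
month the last one decides. Event-free months carry the post-operative
ambient state: `SECOND_STAGE` after a spacer-installing operation,
`OBSERVATION` otherwise, `PJI` before the first operation. Death months
(through censoring) are `DEATH`. This places every operation on the
transition out of its month, which is exactly where operation costs are
charged: leaving `PJI` is the PJI surgery, `SECOND_STAGE → OBSERVATION` is
the second-stage exchange, leaving `NON_PJI_OP` is the unrelated surgery.
For the canonical two-stage course (spacer in month 0, exchange in month 3,
observed into month 4) this yields the chain
`[PJI, SECOND_STAGE, SECOND_STAGE, SECOND_STAGE, OBSERVATION]` with its
five cost terms: one PJI month, the PJI operation, three spacer months, the
second-stage operation, one observation month.

Transition probabilities are pooled counts `P[i,j] = n(i→j)/n(i→·)`. Rows
never visited (small subgroups, e.g. 13 resection-arthroplasty patients)
become unit self-loops with a warning rather than errors; the `DEATH` row
is forced absorbing. Simulation starts at `PJI` and runs for the horizon
(default 30 months).

Payoffs: `C(t) = Σᵢ tᵢ·c̄ᵢ` over state occupancies. Utility weights are
PJI 0.35, second stage 0.7, non-PJI surgery 0.5, observation 0.85, death 0.
The weights are treated as **annual** by default (`annualize=True`, monthly
accrual divided by 12), which puts 30-month totals in the ~2-QALY range;
`annualize=False` reproduces the canonical five-month example verbatim
(1×0.35 + 3×0.7 + 1×0.85 = 3.30). Both conventions are exposed because the
source arithmetic is ambiguous between them; reports state the horizon and
convention used. Monthly stay costs default to 40 000 ₽ (PJI, inpatient),
8 000 ₽ (spacer wait), 30 000 ₽ (non-PJI surgical episode), 2 000 ₽
(observation); per-transition operation costs default to category means
estimated from the fitted records (falling back to 90 000 / 130 000 /
35 000 ₽ for PJI, second-stage and non-PJI surgery). Which transitions
carry operation costs is configurable; the default set is the one implied
by the two-stage worked scenario extended symmetrically to the other
surgical states. A discount-rate hook exists and defaults to 0 (no
discounting). Expected totals are computed analytically by occupancy
propagation (o_{t+1} = o_t P) and agree with Monte-Carlo trajectory means
within sampling error; both routes are exposed.

## Uncertainty

All interval estimates use an m-out-of-n subsample bootstrap: n = 10
subsamples of 80% of the records drawn **without** replacement (the
with-replacement classical bootstrap is available behind a flag), the
estimator re-run on each, and a Student-t interval
`x̄ ± t_{α/2,n−1}·S/√n` formed over the re-estimates, with α = 0.05 by
convention. Intervals for probabilities are clipped to [0, 1] since
t-intervals can overshoot the parameter space. For tree edges whose parent
prefix is absent from a subsample the re-estimate is undefined and skipped;
a reached prefix with an untaken branch contributes 0.

## Synthetic cohort generator

The generator defines the study conditions for every downstream test. It
reproduces the published demographic grid exactly — 600 patients over
treatment × sex × age band (bands <20 through >90), including the 3-patient
excluded one-stage retrospective row — by construction, drawing birthdates
uniformly inside each band relative to the sampled manifestation date
(2005–2015 for retrospective, 2016–2017 for prospective records; only band
membership matters downstream).

Disease courses are simulated month by month: a primary intervention in
month 0 (two-stage methods: spacer installation, then the second-stage
exchange after a normally distributed delay — means 3.5 months for the
>2-month method, 0.7 for 2–3 weeks, 1.6 for 6–8 weeks, 3.0 for partial
two-stage); from month 1 on, relapse and death are competing monthly
Bernoulli events with relapse evaluated first (default 0.02/month relapse,
0.004/month death hazard), plus a small chance (0.004/month) of an
unrelated operation. A relapse triggers a relapse-category operation
(spacer reinstallation under two-stage methods, restarting the second-stage
wait; otherwise debridement-type surgery that resolves the infection with
probability 0.7, an unresolved course ending as `Failure`). Death
terminates the sequence; sequences are capped at 10 operations. Operation
costs are clipped-normal draws by category (means 90 000 / 130 000 /
35 000 ₽, CVs 0.25/0.2/0.3); interval QALY increments scale a clipped-normal
health-state weight (mean 0.6) by interval length. Default horizon:
36 months, so both the 24-month tree and 30-month Markov analyses are fully
covered. Where no published value exists these defaults were chosen once as
clinically plausible magnitudes and are config-level, not hard-coded.

All randomness flows through a single seeded generator: a config (with its
seed) maps to one byte-identical cohort. The generator emulates marginal
structure and event timing only — it has no comorbidity or surgeon effects,
no correlation between demographics and disease course, and its generative
parameters are not fitted to any real cohort — so passing tests demonstrate
the estimators' correctness and calibration behavior, not clinical
conclusions about real patients.

## Cost-effectiveness assembly

Per method and model family, expected QALY and cost totals over the horizon
(tree: 24 months; Markov: 30 months; both configurable and stated in the
report header) are combined into cost per QALY, rounded half-up to two
decimals at display only (internal arithmetic is full-precision — several
published cells are only consistent under this convention, and only those
self-consistent cells are asserted). Methods are ranked by ascending cost
per QALY; ties (never observed in the source tables) break toward higher
QALY, then method code. Tables never mix model families, whose QALY and
cost conventions are not comparable.

## Numerical and testing choices

- Probability normalization is enforced to 1e-9 at every tree node and
  matrix row.
- The parameter-recovery check re-estimates a fixed, clinically shaped
  5-state chain from 500 simulated 30-month trajectories and requires every
  transition probability to lie in a *simultaneous* 95% confidence set
  (exact Clopper–Pearson intervals, Bonferroni-corrected over the 16 free
  entries). Simultaneity is essential: with ~16 marginal 95% checks the
  probability that all pass is only ≈0.6 per replicate, whereas the
  family-wise construction passes ≈95% of replicates, matching the
  experiment's 18-of-20-seeds acceptance rule.
- Monte-Carlo cross-checks (tree path sampling at 1e5 draws, Markov
  trajectory means at 1e4 trajectories) use a 3-standard-error tolerance.
- Problem sizes throughout the test suite (600-patient cohorts, 500–10 000
  trajectories, 1e5 path draws) were chosen so the full suite and the
  acceptance script each run in well under a minute on one CPU while
  keeping sampling error far below the asserted tolerances.

## Known limitations

- The Markov chain is time-homogeneous and memoryless: transition
  probabilities do not depend on age, sex, time since manifestation, or the
  number of prior relapses (semi-Markov and covariate-dependent extensions
  are out of scope).
- Decision-tree states do not encode time, so time-dependent costs and
  late events beyond the horizon are invisible to it.
- Utility and stay-cost defaults are expert-style constants, not estimated
  from data; conclusions are sensitive to them and they should be
  overridden when real EQ-5D and accounting data are available.
- The record CSV schema is this package's own; parsing institutional
  archive formats is out of scope.
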