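# Methods

## The phenotyping problem

Administrative discharge data record every hospital contact with NOMESCO
procedure codes and (Danish-dialect) ICD-10 diagnosis codes, but they were
built for reimbursement, not research. Identifying *that* a reoperation
happened after fracture surgery is easy — any subsequent surgical code in
the same anatomical territory — and is known to have high positive
predictive value. Identifying *why* is hard, because the cause-specific
codes are used inconsistently. `reopcause` implements both halves: a
deterministic finder/classifier for deployment, and a stepwise
algorithm-construction procedure for tuning code sets against a
gold-standard (chart-review) labelled cohort.

## Candidate identification

A contact is a candidate reoperation for an index surgery when all of:

- **chapter** — it carries ≥ 1 procedure code in chapter KA (nervous
  system), KN (musculoskeletal) or KQ (skin);
- **window** — its day offset `d` from the index surgery satisfies
  1 ≤ d ≤ 365. Day 0 is the index contact itself: the index procedure must
  not self-match, so the window is the half-open interval (0, 365] in days.
  Day resolution is the natural resolution of discharge data;
- **region** — some qualifying procedure code carries the index region
  letter (position 3 of KN/KQ/KA codes, one of B–H) or is region-neutral.
  Chapters other than KN have no authoritative positional rule; the
  per-chapter policy is configurable, defaulting to "positional letter if
  it is a region letter, else region-neutral". Region-neutral is the
  permissive reading of "same anatomical area" for skin and nerve chapters;
- **laterality** — the contact side equals the index side, or either side
  is unspecified. An index with unspecified side accepts both sides (the
  symmetric reading of the rule).

Codes sharing a `contact_id` form one candidate; two contacts on the same
day stay separate candidates, because reoperations are counted as
procedures/contacts, not as codes.

**Exclusions.** Planned K-wire removal, external-fixator removal and
chronic-wound surgery (foot ulcer, decubitus, venous disease) are not
reoperations. Registries do not publish canonical code lists for these, so
the shipped defaults are deliberately minimal placeholders — `KNxU19`,
`KNxU09` (procedure rules in "all procedures must match" mode, so a mixed
contact survives) and `DL89`/`DL97`/`DI83` (diagnosis rule in "any
diagnosis" mode) — and should be replaced per deployment via the code-set
config. Exclusion happens before cause classification, so an excluded
K-wire contact is never counted as hardware removal.

## Cause classification

Causes are evaluated per candidate in severity order — infection,
nonunion, re-osteosynthesis, secondary arthroplasty, hardware removal,
wound treatment — and the first firing rule wins; candidates matching
nothing fall through to *other*. Consequences of the ordering:

- infection precedence implements "KQ procedures unrelated to infection":
  a debridement contact with infection evidence labels as infection, a
  plain KQ contact as wound treatment;
- "secondary arthroplasty not caused by nonunion or infection" is resolved
  by precedence rather than by a per-candidate test.

The six-week threshold is fixed at 42 days with the boundary assignments
d ≤ 42 → early re-osteosynthesis, d > 42 → secondary arthroplasty,
d ≥ 42 → hardware removal. The first two windows partition follow-up, so
no candidate can take both revision labels; at d = 42 exactly, hardware
removal is reachable because the re-osteosynthesis patterns differ from
`KNxU`.

At fracture level the most severe candidate label wins, and causes roll up
to composites: major = {infection, nonunion, re-osteosynthesis, secondary
arthroplasty}, minor = {hardware removal, wound treatment}.

**Shipped pattern defaults** are the cause-specific code families with
documented registry usage: `KNxW69`/`KNxW59` + `DT846` (infection),
`KNxT5` + `DT813O`/`DM841` (nonunion), `KNxJ`/`KNxC` + `DT840`–`DT844`
(early re-osteosynthesis), `KNxC` + prosthesis stem `KNxB` (secondary
arthroplasty), `KNxU` (hardware removal), `KQ` (wound treatment). All
patterns are prefix patterns (`KNxU` catches `KNGU29`), with `x` a
single-letter region wildcard, because NOMESCO codes extend named stems.
Real deployments are expected to extend these lists from local step
tables; everything is editable in the YAML/JSON config without code
changes.

## Accuracy statistics

All metrics derive from the 2×2 table (TP, FP, FN, TN) of algorithm vs
gold standard at fracture level:

- sensitivity 100·TP/(TP+FN); PPV 100·TP/(TP+FP); specificity
  100·TN/(TN+FP); NPV 100·TN/(TN+FN). Zero denominators propagate as
  explicit missing values, never as 0 and never as an exception.
- 95% intervals are exact Clopper–Pearson via the beta-quantile
  characterisation, lower bound 0 at k = 0 and upper bound 100 at k = n;
  the test suite checks agreement with a brute-force inversion of the
  exact binomial test.
- Cohen's κ = (p_o − p_e)/(1 − p_e) with the usual marginal-product
  expected agreement; κ := 1 at degenerate perfect agreement (p_e = 1,
  p_o = 1).
- The AUC of a single deployed binary rule is balanced accuracy,
  (sensitivity + specificity)/2 as fractions. This is the quantity a 2×2
  table determines; full ROC traces only exist across builder steps.
- Display rounding is integer percent and two-decimal κ/AUC, half away
  from zero; machine outputs keep full precision.

Published validation tables often print marginals plus the correct
diagonal (all test-positives TP with true positives TrP among them, and
likewise for the negative column); `ConfusionCounts.from_marginals`
rebuilds the four cells as tp = TrP, fp = TP − TrP, tn = TrN,
fn = TN − TrN. This reconstruction is adopted because it reproduces the
printed sensitivity, PPV, κ and AUC simultaneously for the infection,
nonunion, re-osteosynthesis, wound and minor-composite rows of the
reference validation table. Three printed values are *not* reproducible
from their own printed cells under this (or any tried) reading — the
major-composite κ, the hardware-removal κ and the minor-composite AUC —
and one row prints a diagonal larger than its marginal (secondary
arthroplasty), whose cells are instead rebuilt from the cause totals.
These four numbers are excluded from regression tests; everything else is
asserted to round back to its printed value.

## Stepwise algorithm construction

`StepwiseCauseModel` holds a boolean fracture × code-family fire matrix
(firing respects the cause's day window) and binary gold labels.

- **Ranking.** Each family is scored by the likelihood-ratio statistic G²
  of its 2×2 fires × gold table, signed by the direction of association.
  G² is exactly the LR test of the single-predictor logistic regression,
  but computed in closed form it is finite and deterministic under
  complete separation (a family firing only in positives gets a large
  positive score rather than a diverging coefficient). Families that never
  fire score 0. Ties break by higher PPV, then lexicographic name.
- **Composition.** Step k classifies positive when any of the top-k
  families fires. Unions only grow, so sensitivity and the number of
  test-positives are non-decreasing in k (asserted on every trace).
- **Selection.** The deployed step is the κ-argmax over steps, first
  occurrence on ties (parsimony; the choice is otherwise arbitrary).
- **Composites.** The major/minor composite algorithm fires when any
  constituent cause's selected step fires, scored against the composite
  gold label.

The univariate (per-family) reading of "rank by logistic regression" is a
design choice: steps add code families cumulatively, which is what a
sequence of univariate inclusions produces; multivariable selection would
not yield a nested step structure.

## Synthetic registry generator

The generator emulates a one-year national fracture cohort at
discharge-data granularity. Per fracture: a region drawn from weights
proportional to realistic primary-surgery volumes per region (hip and
forearm largest, pelvis smallest), a side, an index date in 2016, an index
contact at day 0, then a true cause drawn from the one-year prevalences
(hardware removal 7.5%, wound treatment 5.4%, re-osteosynthesis 1.7%,
other 1.2%, infection 1.0%, secondary arthroplasty 0.8%, nonunion 0.8%;
~81% no reoperation). Reoperation days are uniform within each cause's
admissible window (≤ 42 for re-osteosynthesis, > 42 for secondary
arthroplasty, ≥ 42 for hardware removal, anywhere in (0, 365] otherwise)
— no timing distribution is published, so uniform is the simplest
assumption consistent with the windows.

**Coding-error model.** A true reoperation contact always carries *some*
surgical procedure code (the surgery was performed and billed); whether it
carries the *cause-specific* codes is the error model. Per cause:
P(correct procedure code), P(correct diagnosis code) and P(both) — the
coupling makes "either" = p + q − p_both. Defaults follow validated
code-usage rates: infection 0.26/0.33/0.10, nonunion 0.18/0.11/0.08,
re-osteosynthesis 0.90/0.07/0.06, secondary arthroplasty 0.03 (miscoded
as a primary prosthesis insertion `KNxB` otherwise), hardware removal and
wound treatment 0.99. When neither correct code is drawn, the decoy is a
plausible miscode: infections become plain skin-surgery contacts
(`KQxE10`), arthroplasties primary prostheses, the rest nonspecific
revision stems.

Real stepwise algorithms reach infection sensitivities far above the
correct-code rates, which proves that informative *adjacent* codes exist
in real data. The generator therefore emits an adjacent code for
infections and nonunions that carry neither correct code: the neighbouring
device-infection diagnosis `DT845` with probability 0.55 (so the full
family union detects ≈ 0.49 + 0.51·0.55 ≈ 0.77 of infections) and the
delayed-union diagnosis `DM842` with probability 0.77 (union ≈ 0.82 of
nonunions). These probabilities are calibrated once, from the published
end-to-end sensitivities, and are part of the study conditions; the
adjacent families are included in the builder's default candidate pool.

**Noise contacts**, at per-fracture rates matching the false-positive and
filtered-contact structure of a national cohort: ER procedures in the
index region (0.9%, become "other" false positives), new fractures in
other regions (0.16%), chronic-wound surgery with its wound diagnosis
(0.11%, caught by exclusions), K-wire (0.64%) and external-fixator (0.10%)
removals (caught by exclusions), contralateral procedures (1.2%) and
other-region surgery (10%, both filtered by the finder). Reoperation-event
laterality is missing at rate 0.3 by default (index laterality is always
recorded, as it is in surgeon-reported index data). Optional modes:
censoring (death before follow-up end) truncates events and, when it
precedes the drawn reoperation, reverts the gold label to
no-reoperation; a multi-reoperation mode adds a second, strictly less
severe contact to exercise the severity roll-up.

**What the generator does not emulate:** real contact microstructure
(transfers, outpatient series), correlated coding behaviour within
hospitals, cause-specific seasonality, infected nonunions (acknowledged as
indistinguishable in coded data), and any calibration to patient-level
data. Passing the synthetic recovery tests therefore shows the *pipeline
logic* is correct under the stated error model — not that the shipped
default code sets achieve any particular accuracy on a real registry;
that always requires local validation against charts.

## Numerical and engineering choices

- Dates are ISO-8601 at day resolution; ingest validates every row and
  reports rejects with line numbers (accepted + rejected = input, always).
- All randomness flows through one `numpy` generator seeded from the
  config; identical configs give bit-identical cohorts.
- Confusion-table metrics with zero denominators are `None`, and reports
  preserve them as missing.
- Problem sizes used by the test suite and the acceptance script —
  cohorts of 600–20,000 fractures, twenty replicates of 2,347 for the
  stepwise-gain measurement — were chosen to keep Monte-Carlo error well
  below the effects being demonstrated while remaining quick on one CPU.

## Known limitations

- Default exclusion code lists are placeholders; deployments must supply
  local lists.
- The laterality encoding of a real extract (side markers vs a dedicated
  field) must be mapped onto left/right/unspecified via the I/O dialect;
  no dialect ships for any specific national register.
- The builder searches the configured candidate pool only; it does not
  mine new codes from the data.
- "Other" is a fallback, not a modelled cause; its PPV on noisy data is
  structurally low (ER-visit false positives land there).
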