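# reopcause

Identify **reoperations after fracture surgery** — and *why* they happened —
from coded health-administrative data, and quantify how well any given code
set does it.

Hospital discharge registers (the Danish National Patient Register is the
archetype) record every contact with NOMESCO surgical procedure codes
(`KNGJ21`: chapter `KN` musculoskeletal, region `G` knee/lower leg) and
ICD-10 diagnosis codes in the Danish dialect (`DT846`, no dot). They are
complete and cheap, but the codes for *causes* of secondary surgery are
used inconsistently: in validated cohorts the correct infection procedure
code appears in only about a quarter of true infections. `reopcause` is for
registry epidemiologists who need to phenotype reoperations and their
causes from such data, and to report how accurate the phenotype is.

## What it does

1. **Find candidate reoperations.** For each index osteosynthesis, every
   contact with a KA/KN/KQ procedure code within days 1–365, in the same
   anatomical region (region-neutral codes pass) and on a compatible side
   (same side, or laterality missing). Configurable exclusions (planned
   K-wire/external-fixator removal, chronic-wound surgery) are moved to an
   excluded stream with machine-readable reasons.
2. **Classify the cause.** Stepwise "or"-composed code-set algorithms per
   cause, evaluated in a fixed severity order — infection > nonunion >
   early re-osteosynthesis > secondary arthroplasty > hardware removal >
   wound treatment > other — with six-week day windows (re-osteosynthesis
   at day ≤ 42, secondary arthroplasty at day > 42, hardware removal at
   day ≥ 42). Fractures with several reoperations take the most severe
   label; causes roll up into major/minor composites.
3. **Validate.** Against gold-standard labels: sensitivity
   = 100·TP/(TP+FN), PPV = 100·TP/(TP+FP), specificity, NPV, exact
   Clopper–Pearson 95% intervals, Cohen's κ = (p_o − p_e)/(1 − p_e), and
   the AUC of a deployed binary rule as balanced accuracy
   (sens + spec)/2.
4. **Rebuild algorithms from data.** `StepwiseCauseModel` ranks candidate
   code families by their univariate association with the gold label
   (the likelihood-ratio statistic of the single-predictor logistic fit,
   computed in closed form from the 2×2 table), composes them into
   cumulative "or" steps, scores every step, and selects the κ-maximal
   step. Sensitivity is non-decreasing in the step number; PPV typically
   decreases — the classic trade-off.
5. **Simulate.** A synthetic registry generator with a per-cause
   coding-error model (probability of carrying the correct procedure code,
   the correct diagnosis code, both, or only an adjacent substitute code)
   plus noise contacts (ER visits, contralateral and other-region surgery,
   chronic wounds, K-wire removals), so the whole pipeline is testable
   without access to patient data.

## Worked example

```python
import reopcause as rc

cohort = rc.generate(rc.SyntheticConfig.default(2000, seed=7))   # known ground truth
result = rc.run_pipeline(cohort.events, cohort.index_surgeries)  # find + exclude + classify
reports = rc.evaluate(result.fracture_table, cohort.gold_labels)

pool = rc.default_pattern_pool()[rc.CauseLabel.INFECTION]
model = rc.StepwiseCauseModel.from_cohort(
    result.retained, cohort.index_surgeries, cohort.gold_labels,
    rc.CauseLabel.INFECTION, pool)
print(model.fit().summary())
```

```
Stepwise algorithm construction: infection
fractures: 2000  positives: 20
selected step: 3 (kappa-maximal)

step      sens % (CI)       PPV % (CI)  spec %  kappa   AUC  added group
  1        60 (36-81)     100 (74-100)   100.0   0.75  0.80  device_infection_adjacent_DT845
  2        85 (62-97)     100 (80-100)   100.0   0.92  0.93  infection_procedures_KNxW69_KNxW59
  3*      95 (75-100)     100 (82-100)   100.0   0.97  0.97  infection_diagnosis_DT846

* kappa-maximal (deployed) step
```

Reading it: 20 of the 2,000 synthetic fractures truly had an infection
reoperation. No single code family finds more than 60% of them — the
coding-error model suppresses the specific codes at realistic rates — but
each "or" step adds sensitivity without losing precision here, and the
κ-maximal step 3 finds 95%. The deployed *default* algorithm (specific
codes only) reaches just 35% sensitivity on the same cohort, which is
exactly the registry problem the stepwise construction repairs. The same
cohort's full accuracy panel comes from `rc.accuracy_table(reports)`.

Shell users get the same stages as subcommands:

```
reopcause simulate --n 2000 --seed 7 --out sim/
reopcause identify --events sim/events.csv --surgeries sim/index_surgeries.csv --out ident/
reopcause classify --candidates ident/candidates.csv --surgeries sim/index_surgeries.csv --out cls/
reopcause evaluate --fractures cls/fracture_causes.csv --gold sim/gold_labels.csv --out eval/
reopcause build    --candidates ident/candidates.csv --surgeries sim/index_surgeries.csv \
                   --gold sim/gold_labels.csv --out build/
```

## Layout

| module | role |
| --- | --- |
| `reopcause.codes` | NOMESCO/ICD-10 pattern matching, region extraction, laterality |
| `reopcause.codesets` | per-cause algorithms, exclusion rules, YAML/JSON config |
| `reopcause.registry_io` | validated readers/writers for event, surgery and gold tables |
| `reopcause.finder` | candidate identification and exclusions |
| `reopcause.classifier` | cause assignment, severity roll-up, composites |
| `reopcause.stats` | confusion counts, exact intervals, κ, AUC, report writer |
| `reopcause.builder` | `StepwiseCauseModel` / `StepwiseResults` |
| `reopcause.synth` | synthetic registry generator and generation report |
| `reopcause.cli` | `reopcause` command-line tool |

See `docs/methods.md` for the modelling assumptions, default parameters and
known limitations.
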