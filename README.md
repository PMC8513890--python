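# cdclaims

Case-identification ("phenotyping") algorithms for **Crohn's disease (CD)**
in monthly health-insurance claims data, together with the complete
chart-review validation machinery around them: age-stratified sampling with
survey weights, two-reviewer adjudication, diagnostic-validity statistics
with exact confidence intervals, chance-corrected agreement coefficients,
weighted extrapolation to the source cohort, and a seeded synthetic claims
generator with known ground truth.

It is written for pharmacoepidemiologists and health-services researchers
who extract disease cohorts from administrative claims databases and need to
quantify — or simulate — how well a coding rule identifies true cases.

## The algorithms

A claims table is a list of monthly billing lines (patient, month, code
system DX/RX/PR, code, suspected-diagnosis flag).  A patient-month meets:

- **IC-A** — carries a *confirmed* (non-suspected) ICD-10 diagnosis matching
  the target prefix **K50** (Crohn's disease) and no confirmed diagnosis
  matching the exclusion prefixes **K51** (ulcerative colitis) or **M35**
  (Behçet's disease) in the *same month*;
- **IC-B** — IC-A plus a CD prescription code in the same month;
- **IC-C** — IC-A plus a CD prescription *or* surgery code in the same month.

By construction B ⊆ C ⊆ A month-wise and patient-wise.  A patient is in a
cohort when at least one month qualifies (a repeat-month threshold is
available as a knob).

## The validation design

Criterion-positive and criterion-negative patients are sampled with
age-stratified random sampling (proportional allocation, largest-remainder
rounding, Horvitz–Thompson weight `N_stratum / n_stratum`), each sampled
chart is categorized independently by two reviewers as
confirmed / suspected / negative (a decisive third review resolves
disagreements), and the 2×2 table of criterion vs chart diagnosis gives

```
sens = TP/(TP+FN)   spec = TN/(TN+FP)   PPV = TP/(TP+FP)   NPV = TN/(TN+FN)
```

each with an exact Clopper–Pearson 95% interval from beta quantiles
(`lower = B(α/2; x, n−x+1)`, `upper = B(1−α/2; x+1, n−x)`), the right family
when counts sit on the boundary (x = 0 or x = n).  Review reliability is
summarized by Cohen's κ, linear/quadratic weighted κ (Fleiss–Cohen–Everitt
variance), and Gwet's AC1 (robust to skewed category prevalence).

## Worked example

A full synthetic validation study — generate a 20,000-patient hospital
claims database, extract the cohorts, sample 100 positives / 200 negatives
per criterion, simulate the dual chart review, adjudicate, and score:

```python
from cdclaims import SimConfig, run_study, CaseDefinition, estimate_true_count

result = run_study(SimConfig(), criteria=("A", "B"), seed=0)
c = result.counts
print(f"enrolled={c.n_total}  IC-A={c.n_a}  IC-B={c.n_b}  IC-C={c.n_c}")
for crit in ("A", "B"):
    m = result.criteria[crit].metrics[CaseDefinition.CONFIRMED_ONLY]
    p = m.ppv
    print(f"IC-{crit}: PPV {p.estimate:.3f} (95% CI {p.ci_low:.3f}-{p.ci_high:.3f}), "
          f"sens {m.sensitivity.estimate:.3f}, spec {m.specificity.estimate:.3f}")
print("estimated true CD among IC-A positives:",
      estimate_true_count(c.n_a, result.criteria["A"].ppv()))
```

prints

```
enrolled=20000  IC-A=185  IC-B=165  IC-C=165
IC-A: PPV 0.800 (95% CI 0.708-0.873), sens 1.000, spec 0.909
IC-B: PPV 0.920 (95% CI 0.848-0.965), sens 0.989, spec 0.961
estimated true CD among IC-A positives: 148
```

Read: of 20,000 synthetic patients, 185 met the diagnosis-code-only
criterion but only 80% of a 100-case stratified sample were chart-confirmed
CD — diagnosis codes alone admit look-alike diseases (infectious
enterocolitis, intestinal Behçet's, ...).  Requiring a same-month CD
prescription (IC-B) shrinks the cohort to 165 and lifts the PPV to 0.92.
Applying the PPV to the whole extracted cohort estimates ⌊185 × 0.80⌋ = 148
true CD patients.  Note IC-C = IC-B here: months with a CD surgery code
essentially always carry a CD prescription too.

The same stages are scriptable from the shell:

```bash
cdclaims generate --seed 3 --out-dir data/
cdclaims extract  --claims data/claims.csv --out data/inclusion.csv
cdclaims sample   --inclusion data/inclusion.csv --patients data/patients.csv \
                  --criterion A --seed 5 --out data/sample.csv
cdclaims validate --sample data/sample.csv --review data/review.csv
cdclaims agree    --ratings data/ratings.csv --pair r1:r2
```

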