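# Methods

## Scope and model

`cdclaims` implements month-level case-identification rules over
administrative claims and the survey-style machinery used to validate such
rules against chart review.  The statistical content is deliberately plain:
every validity metric is a binomial proportion on its own denominator, the
sampling design is stratified simple random sampling without replacement,
and reliability is summarized by standard chance-corrected agreement
coefficients.  The package's value is in wiring these pieces together
correctly — month-scoped exclusions, suspected-flag handling, weights,
adjudication, boundary-safe intervals — and in a generator that produces
claims data whose ground truth is known.

## Inclusion criteria

The unit of evaluation is the patient-month (Japanese claims are billed
monthly; days are never parsed).  Criterion A requires a confirmed
(non-suspected) diagnosis line matching a target ICD-10 prefix and no
confirmed line matching an exclusion prefix in the same month.  Three
choices deserve emphasis:

- **Prefix matching.** Codes are normalized (uppercase, dots stripped) and
  matched by leading substring, so the chapter prefix `K50` covers
  `K50.0`–`K50.9`.  Exclusion prefixes are checked prefix-aware against the
  target prefixes at codebook construction (a target `K50` and an exclusion
  `K50.1` would silently fight otherwise).
- **Suspected flags.** Only confirmed diagnoses count — in *both*
  directions.  A suspected-flag K50 never includes a month, and a
  suspected-flag K51/M35 never vetoes one.
- **Month-scoped exclusion.** A confirmed exclusion code in another month
  does not veto a clean month; "same month" is taken literally.

Patient-level inclusion needs ≥1 qualifying month by default;
`min_qualifying_months` raises that for repeat-detection protocols.  The
first qualifying month is always the earliest flagged month.

The observation window is a required configuration value (default
2015-01 … 2019-12) rather than a constant.

## Validity statistics

Sensitivity, specificity, PPV and NPV each get an exact Clopper–Pearson
interval computed from beta quantiles.  The exact family is used because
validation tables routinely contain boundary cells (x = n positives
confirmed, zero false negatives), where Wald and Wilson intervals are wrong
or degenerate.  A metric with a zero denominator is reported as *undefined*
(`None`), never 0 or 1: with no false negatives the NPV denominator is TN
alone, and an empty denominator carries no information.

Extrapolation of a sampled 2×2 back to the source cohort multiplies each
arm by its sampling weight (population arm size / sampled arm size) and
floors to whole patients; `estimate_true_count(n, ppv) = ⌊n·ppv⌋` follows
the same convention.  Flooring, not rounding, is the package's convention
for converting estimated fractional patients to counts.

Sample-size planning uses the normal approximation
`n = ⌈z² p(1−p)/d²⌉` for a target CI half-width `d` (planning proportion
defaults to the worst case 0.5; d = 0.1 at 95% gives 97, commonly rounded
up to a round 100 in study protocols).  No attempt is made to plan the
negative arm for sensitivity/specificity at realistic disease prevalence —
for a prevalence of ~5.6 per 10,000 that demand is in the tens of thousands
of charts and outside any single-center design this package targets.

## Sampling and adjudication

Within each arm, allocation across age bands (default 10-year bands at the
window start; the band width is a parameter because published designs
rarely state it) is proportional with largest-remainder rounding, capped at
stratum sizes with deterministic redistribution.  Each sampled case carries
the Horvitz–Thompson weight `N_h/n_h`, so weights within an arm sum back to
the arm's population size up to rounding.  A pool smaller than the request
raises an error; there is no silent take-all.

When validating criterion X, the negative pool is the roster complement of
X.  For the prescription-augmented criterion B this places A∖B patients in
the negative pool — a deliberate, logged choice; designs that only ever
review the diagnosis-only complement should sample with `criterion="A"` and
re-score.

Adjudication is the consensus rule: two concordant reviews stand; a
discordant pair is decided by the third review (in simulation the third
reviewer draws from the same confusion model unless configured otherwise).
A discordant pair without a third review is an error listing the cases, not
a silent drop.

## Agreement coefficients

Cohen's κ, weighted κ and Gwet's AC1 all consume the same q×q
cross-tabulation; inter-rater and intra-rater reliability are the same code
path applied to different rating pairs.  Weighted κ defaults to linear
weights `1 − |i−j|/(q−1)` over the clinical ordering confirmed < suspected
< negative (both the scheme and the ordering are configurable, and reports
label the scheme used).  Variances: Fleiss–Cohen–Everitt large-sample
formula for both κ variants (the unweighted case is the identity-weight
specialization), Gwet's linearized estimator for AC1; CI bounds are
truncated to [−1, 1].  A table with all mass in one category has chance
agreement 1 and κ is reported as undefined rather than coerced.

## The synthetic generator

The generator emulates a single IBD-specialist hospital's claims feed —
the setting in which such validation studies are run — with a latent
three-way truth per patient (CD / mimic disease / neither) and month-level
coding mechanisms:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 20,000 | roster size (hospital scale, desk-scale runtime) |
| `prevalence_cd` | 0.008 | P(true CD) among visitors |
| `prevalence_mimic` | 0.0016 | P(a K50-attracting mimic disease) |
| `mimic_spectrum` | 0.4/0.2/0.1/0.1/0.1/0.1 | infectious enterocolitis : intestinal Behçet's : drug-induced enterocolitis : intestinal TB : stenosis : cirrhosis |
| `p_k50_given_cd` | 0.90 | per visit-month confirmed K50 rate, true CD |
| `p_k50_given_mimic` | 0.30 | same, mimic diseases (miscoding) |
| `p_excl_code_given_behcet` | 0.50 | Behçet's own M35 lands in the K50 month |
| `p_rx_given_cd_coded` | 0.85 | CD prescription in a K50 month, true CD |
| `p_rx_given_mimic_coded` | 0.03 | same, mimics (trial therapy, miscoding) |
| `p_pr_given_rx_absent` | 0.05 | CD surgery in a prescription-free K50 month |
| `mean_visit_months` | 6.0 | truncated-Poisson billing months per patient |
| `p_k50_suspected` | 0.01 | rule-out suspected-flag K50 on non-CD patients |
| `p_confirmed_given_cd` | 0.965 | chart review confirms (vs suspects) true CD |
| `reviewer_confusion` | ≈0.93–0.98 diagonal | per-reviewer category confusion |
| `source_distribution` | 0.74/0.24/0.00/0.02 | confirmed-diagnosis source a/b/c/d |

Mechanisms worth noting: intestinal Behçet's disease is the one mimic whose
*own* diagnosis code (M35.2) matches an exclusion prefix, so its K50 months
are vetoed whenever the codes coincide — the minimal mechanism that makes
the same-month exclusion rule consequential.  Surgery codes are emitted only
for true CD patients' prescription-free K50 months, which keeps criterion C
nearly identical to B, as specialist-center data show.  Non-CD patients
accrue filler diagnoses and occasional suspected-flag K50 lines, so the
criterion-negative pool is realistic and the suspected-flag rule is
exercised end-to-end.

**Calibration.** Defaults were set from the closed-form identity
P(CD | IC-A) = π_cd·a_cd / (π_cd·a_cd + π_mimic·ā_mimic), where a_• is the
chance of ≥1 qualifying month, targeting P(CD | IC-A) ≈ 0.86 and a
chart-confirmed PPV ≈ 0.83 for the diagnosis-only criterion, rising
substantially under the prescription requirement — the qualitative
structure single-center validations report.  Monte-Carlo verification over
20 replicates at the default scale gives mean P(CD | IC-A) ≈ 0.86 and mean
pipeline PPV(IC-A) ≈ 0.82, with PPV(IC-B) > PPV(IC-A) in every replicate.
The default scale (20,000 patients, IC-A pool ≈ 150–220) is chosen so the
standard 100/200 sampling design always has enough positives while a full
study replicate runs in well under a second; a hospital-census scale
(e.g. 82,898 patients at prevalence ≈ 0.003, IC-A pool ≈ 255) is a config
choice, not a different code path.

**What the generator does not model**, and hence what passing tests do not
establish about real data: no longitudinal disease progression, treatment
switching or discontinuation (so it cannot probe the "IC-B misses patients
off therapy" failure mode beyond the rx-rate parameter); no false-negative
*coding* structure validated against real data (`p_k50_given_cd < 1` is a
guess, flagged in the config docs); no main-disease field (some claims
formats mark one diagnosis per bill as primary; the criteria here cannot
condition on it); no costs, dosing, or realistic code dictionaries (the
shipped codebook's RX/PR entries are named placeholders).  Reviewer errors
are independent across reviewers and cases, which understates the
correlated ambiguity of genuinely hard charts and therefore likely
overstates agreement coefficients relative to a real dual review.

## Numerical and degenerate-input choices

- Floor operations add 1e-9 before truncation to absorb float
  representation error (2.55 × 83 must floor to 211, not 210).
- Stratified allocation breaks remainder ties by stratum label, making
  samples a pure function of (pool, n, seed).
- `run_study` splits its seed into generation / sampling / review streams
  via `SeedSequence`, so the three stages are independently reproducible.
- Empty inputs: empty claims tables classify to an empty result (counts
  0/0/0/0); empty rating vectors and empty samples raise; an empty review
  subset in a study is reported as absent agreement rather than an error.
- The dual-review fraction for reliability defaults to 0.20 of the sampled
  cases, a design parameter rather than a reproduction of any particular
  study's count.

## Known limitations

Single-center specialist settings inflate PPV relative to general practice
(prior probability of CD is high); the generator inherits this by
construction, and nothing here supports transporting a validated PPV to a
database with different case mix.  The agreement module is strictly
pairwise (two raters or two passes); multi-rater generalizations (Fleiss κ,
multi-rater AC1) are out of scope.  Real receipt-format parsing (レセプト,
DPC exports) is out of scope — input is the package's own delimited schema.
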