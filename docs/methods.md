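# Methods

## The proxy construction

The package estimates MS disability from German statutory-health-insurance
claims by a deterministic rule cascade over coded evidence in an assessment
window around an index date. Three evidence channels feed the cascade:

1. **Symptom diagnoses.** ICD-10-GM codes are mapped by a catalog to an
   MS-related symptom, a functional system, and a severity tier (mild /
   moderate / severe). A symptom's diagnosis evidence *qualifies* only under
   the claims validation convention: at least one inpatient diagnosis, or at
   least two outpatient diagnoses flagged *gesichert* (confirmed) on distinct
   service dates. A symptom qualified at several tiers is counted once, at
   the highest tier — one clinical problem is one unit of evidence.
2. **Symptom-associated drugs and therapies.** ATC prescription codes and
   OPS procedure codes mapped by the catalog at a severity tier; distinct
   codes are counted per tier, and a single event suffices (prescriptions
   need no confirmation rule). Treatment escalation (e.g. spasticity:
   descriptor only → mild; plus baclofen → moderate; plus intrathecal pump →
   severe) is encoded as separate catalog rows at different tiers rather
   than as a runtime escalation rule, keeping the cascade a pure function of
   counted evidence.
3. **Special-role codes.** Fampridine (N07XX07), gait disturbance
   (R26.0/.1/.2/.8), paraplegia, tetraplegia, bed confinement (R26.3), and
   the ambulation-aid product groups (walking stick 10.50.01, wheelchair
   18.50/18.51, chair/special bed 19.40.01). Aids and fampridine flag from
   any single event; the plegia and bed-confinement diagnoses require the
   qualification rule. Aid codes match by product-group stem (prefix), as do
   ICD codes at whatever granularity the catalog states.

The cascade is evaluated top-down from step 9 to step 1; the first
satisfied condition assigns the step, and step 0 means no qualifying
evidence of any kind. Because conditions for high steps (ambulation aids,
plegias, bed confinement) are checked before symptom-count conditions, the
cascade equals the maximum over independently evaluated step predicates —
a property the test suite verifies by exhaustive enumeration over all
boolean-flag combinations × diagnosis counts 0–5 per tier × drug counts 0–4
per tier (13,824,000 profiles) against a vectorized independent oracle.

Step 9 additionally requires the patient to be alive at the end of the
observation period; vital status is an input derived from the deaths table
against the study end date, never inferred from claims.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| window | 90 days before and after the index date, inclusive | "3 months" is implemented as fixed 90-day arms for reproducibility; month arithmetic is ambiguous |
| outpatient confirmation | 2 confirmed diagnoses on distinct dates | the weakest defensible reading; a stricter distinct-calendar-quarter variant is available (`require_distinct_quarters`) |
| proxy 0 → 1 imputation | on, in the validation pathway only | reference cohorts of treated MS patients contain no EDSS 0.0; the engine itself still reports 0 |
| step-2 evidence | diagnoses only | two mild-associated drugs without diagnoses remain step 1, following the cascade's printed form literally |
| step-5 "≥4 moderate" | diagnoses only | moderate drugs never mix into the diagnosis count |
| cohort periods | 12 months = 365 days baseline and follow-up | calendar-month arithmetic avoided for the same reason as the window |
| cohort exclusion codes | pregnancy chapter `O`, demyelinating `G36`/`G37` stems | configurable; published exclusion lists are not public |

EDSS rescaling floors half-points (1.0–7.5 → integer step) and groups
8.0–9.5 as "≥8", since those scores share the construct of lost ambulation.
The classifier schemes — eight-fold (1…7, ≥8), three-fold (1–3, 4–5, ≥6),
binary (<6, ≥6) — are nested coarsenings; MSE/MAE use the numeric encoding
with "≥8" as 8 (its lower bound, matching the flooring convention). A
clinician EDSS of 0.0, should one occur, maps to class 1 with a warning so
both scales share a domain and confusion matrices stay square. A proxy step
of 9 (which has no rescaled-EDSS counterpart) folds into the "≥8"/"≥6"
groupings.

Per-class Cohen's κ is the κ of the 2×2 one-vs-rest table. For the binary
scheme the κ of the two classes is algebraically identical (the 2×2 table
of one class is the role-swap of the other); the suite asserts this. Macro
F1 averages *unrounded* per-class F1 values over the classes present in
truth or prediction; classes absent from both carry no information and are
excluded. Metrics are carried unrounded everywhere, with 2-decimal rounding
applied only for display.

Degenerate-table conventions: PPV = 0 when there are no positive
predictions; F1 = 0 when PPV + sensitivity = 0; κ = 0 when expected
agreement is exactly 1. An optional percentile-bootstrap CI for κ is
provided for exploratory use only; it is not validated against any
published interval.

## The synthetic-data generator

Each patient receives a latent trajectory of true disability steps: the
initial step is drawn from a bimodal distribution matching the validation
cohort's index EDSS categories (18/23/27/11/4/9/7/1 % for steps 1…≥8), and
subsequent measurements follow a persistence-dominated ±1 random walk.
Measurement counts per patient run 1–18 with mean ≈ 6.2 (shifted Poisson,
clipped). Each step implies a symptom burden and ambulation state consistent
with the cascade's thresholds (burden is drawn conditional on the step —
exact control, no rejection sampling), and the burden emits claims events
through capture probabilities:

* diagnosis capture by severity — mild 0.25, moderate 0.45, severe 0.85.
  These are plausible, tunable values: published sources describe the
  severity gradient qualitatively but print no per-severity rates;
* aid capture — walking stick 0.22 and wheelchair 0.86 (both published
  observed capture fractions), chair/bed 0.85 (no published value; set near
  the wheelchair rate as reimbursed equipment of similar salience);
* drug emission by severity (mild 0.20 / moderate 0.30 / severe 0.50,
  plausible defaults) and an outpatient-confirmation probability of 0.9,
  with each captured diagnosis emitted either as one inpatient event or as
  an outpatient pair on distinct dates.

Event dates are jittered uniformly within ±60 days of the measurement date;
measurement dates within a patient are spaced by more than two window
widths, so every event belongs to exactly one assessment window.
All randomness flows through one seeded `numpy` generator; identical seeds
give byte-identical output tables.

At capture 1 the emitted events are exactly canonical evidence for each
step and the engine recovers the latent step for 100 % of measurements;
the burden extras are constructed never to cross a step boundary (e.g. a
step-4 fampridine patient draws no moderate or severe symptoms, since any
would promote the step to 5). Lowering mild/moderate capture strictly
increases the under-predicted fraction, and under the default captures the
binary classifier's macro F1 exceeds the eight-fold classifier's — the
qualitative signature of claims-based disability proxies.

What the generator does **not** emulate: real coding frequency and
co-occurrence structure of ICD-10-GM beyond the catalog's symptom list,
relapses and treatment lines, miscoding, or regional/provider effects.
Passing round-trip and ordering tests therefore shows that the engine
implements the cascade correctly and responds to under-capture in the
documented direction — not that the proxy achieves any particular accuracy
on real claims.

## Problem sizes and numerical choices

The simulation-based checks use 500 patients (≈3,000 measurements), chosen
as the smallest cohort at which the stochastic ordering properties are
stable across seeds. The published-counts reproduction is exact arithmetic
on 13 fixed 2×2 tables and uses no randomness. Dates are ISO-8601; all
intervals are closed on both ends; insurance coverage intervals merge when
adjacent within one day. Scores serialize with one fractional digit.

## Known limitations

* The shipped catalog's severity tiers for entries beyond the special-role
  codes are demonstration placeholders; a production analysis must supply an
  institution-curated 69-symptom catalog (the schema is documented and
  validated, and `validate-catalog` reports on any supplied file).
* The cascade reads only structured claims; disability documented solely in
  clinical notes is invisible to it, so mild disability is systematically
  under-estimated — by design the proxy is most trustworthy as a binary
  severe-disability (≥6 vs <6) classifier.
* Cohort selection implements the filter sequence generically; subtype
  classification (RRMS vs progressive MS) and comorbidity scoring are out
  of scope.
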