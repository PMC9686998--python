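# Methods

This note documents the models, conventions and numerical choices behind
`sepscreen`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scores

**NEWS.** The 2012 Royal College of Physicians chart, not NEWS2: no
hypercapnic SpO₂ scale, AVPU rather than ACVPU. Seven components —
respiratory rate, SpO₂, supplemental oxygen (0 or 2 points), temperature,
systolic BP, heart rate, AVPU — each banded to 0–3 points, total 0–20. Band
tables ship as versioned YAML (`src/sepscreen/data/bands.yaml`) guarded by a
SHA-256 checksum; at load time every numeric parameter's bands are swept
exhaustively at the parameter's resolution to prove they partition the
admissible range with no gap or overlap. Temperature bands are defined at
one-decimal precision and inputs are rounded to one decimal before lookup
(38.0 °C scores 0, 38.1 °C scores 1). The positivity rule is **NEWS ≥ 5**
throughout.

**qSOFA.** One point each for RR ≥ 22 /min, SBP ≤ 100 mmHg, and altered
mentation (GCS < 15, or AVPU ≠ A when only AVPU is charted); positive at
≥ 2.

**GCS → AVPU.** 15→A, 13–14→V, 9–12→P, 3–8→U, configurable. Only the
A/not-A boundary affects NEWS and only GCS < 15 affects qSOFA, so the
mapping fixes that boundary at 15 consistently for both scores; the interior
cut points matter only to users who re-band them.

**SOFA.** Six organ components, 0–4 each:

| organ | input | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|
| respiration | PaO₂/FiO₂ mmHg | < 400 | < 300 | < 200 | < 100 |
| coagulation | platelets ×10⁹/L | < 150 | < 100 | < 50 | < 20 |
| liver | bilirubin µmol/L | ≥ 20 | ≥ 33 | ≥ 102 | > 204 |
| cardiovascular | MAP / vasopressor | MAP < 70 | any vasopressor | — | — |
| cns | GCS | 13–14 | 10–12 | 6–9 | < 6 |
| renal | creatinine µmol/L | ≥ 110 | ≥ 171 | ≥ 300 | > 440 |

Conventions for ED extracts: PaO₂ is accepted in kPa or mmHg with an
explicit unit tag (1 kPa = 7.50062 mmHg), never inferred. Vasopressor dose
rates are generally absent from ED data, so any vasopressor flag scores the
cardiovascular component 2 and the dose-graded 3–4 levels are not assigned;
MAP < 70 mmHg without vasopressors scores 1. When no GCS is recorded the
AVPU level is inverted through the conversion table (A→15, V→13, P→10,
U→3 — the upper GCS bound of each level, a conservative choice affecting
only the CNS component).

**SpO₂/FiO₂ fallback.** Without a blood gas, respiration is scored from the
S/F ratio using the published equivalence S/F 315 ↔ P/F 300 and S/F 235 ↔
P/F 200, extended linearly (S/F = 0.8·P/F + 75) to the 400 and 100 cut-offs
(S/F 395 and 155). The linear relation is invalid once the oximeter
saturates: above 97 % a room-air patient scores 0, and on supplemental
oxygen SpO₂ is capped at 97 before the ratio is formed. The component is
monotone non-increasing in S/F by construction, and its provenance is
recorded as `imputed`.

## Sepsis-3 adjudication

A presentation is **complete** iff every input needed for both NEWS and
qSOFA is resolvable (the qSOFA inputs are a subset of the NEWS inputs, and
mentation resolves from either GCS or AVPU). Completeness filtering is the
only exclusion; labs are not part of it because the lab rules below make
the liver and respiration components always resolvable, while a genuinely
missing platelet count, MAP or creatinine raises a named error rather than
silently scoring 0.

Imputation: missing bilirubin ⇒ assumed below the 20 µmol/L threshold
(liver 0, `imputed`); missing PaO₂ ⇒ S/F fallback. Chronic-disease masking:
an ICD-10 discharge code contributes an organ to the mask iff its label
contains "chronic" but not "acute" (case-insensitive) *and* its code matches
the organ's prefix set (circulation I; coagulation D65–D69 inclusive; renal
N0x–N3x; liver K7; nervous G; respiration J). Masked components are forced
to 0 with provenance `masked`. Baseline SOFA is taken as 0 for these
community presentations, so "SOFA ≥ 2" equals "rise of ≥ 2"; masking is the
retrospective substitute for a true baseline correction, and it can only
lower the score — label flips go one way, sepsis → no-sepsis.
Suspected infection is an input flag (chart review), never computed.

## Diagnostic accuracy

Sensitivity, specificity, PPV, NPV and accuracy are binomial proportions;
each carries a Clopper–Pearson exact 95 % interval from beta quantiles
(lower 0 at k = 0, upper 1 at k = n). A zero denominator yields an
`undefined` flag rather than NaN. Reported percentages round half-up,
matching how such tables are printed; internal values keep full precision.

`reconstruct_confusion` inverts a printed summary: tp = ⌊sens·n₊ + 0.5⌋,
tn = ⌊spec·n₋ + 0.5⌋, with fn/fp as complements so group sizes are exact.
Round-half-up on tp and tn (rather than on fn/fp) is the convention that
reproduces all derived cells of the published presentation simultaneously;
the round trip `metrics(reconstruct(s, p))` recovers s and p to within half
a count of the relevant denominator.

ROC curves sweep the distinct observed score values from +∞ downward
(positivity: score ≥ threshold) with no intermediate-point dropping, so the
trapezoidal AUC is exactly the tie-corrected Mann–Whitney U/(n₊·n₋). The
AUC interval defaults to DeLong's placement-value variance (normal
approximation, clipped to [0, 1]); a degenerate variance (e.g. perfectly
separable data) falls back to a seeded stratified bootstrap (default 2000
replicates) with a warning, and the method used is recorded in the report.

## Conditional permutation importance

A seeded `RandomForestClassifier` (default 500 trees, `min_samples_leaf` 5,
out-of-bag scoring) is fitted on the seven raw vitals — SpO₂, FiO₂, AVPU
(ordinal A<V<P<U), SBP, temperature, HR, RR — not on their NEWS points.
Importance of variable j is the mean decrease in per-tree out-of-bag AUC
when j is permuted, averaged over trees and repetitions (default 50);
`spread` is the SD over repetitions. Permutation is *conditional*: within
each tree, OOB samples are stratified by the split points the tree itself
uses on covariates correlated with j, and j is permuted within strata, so
signal shared with correlated vitals is not double-counted. Interpretation:
model AUC 0.80 with importance 0.09 means a model without that variable
would sit near 0.71.

Numerical choices: the conditioning set per variable is the (at most 3)
covariates with |Spearman ρ| ≥ 0.2; each conditioning variable's per-tree
split points are thinned to at most 2 quantile cuts. Both caps exist
because sklearn trees are deep — using every split point yields
near-singleton cells in which permutation degenerates to the identity and
all importances collapse toward 0 at ED-cohort sample sizes (a few hundred
OOB samples per tree). With the conditioning set empty (or
`conditional=False`) the procedure reduces exactly to classical permutation
importance. Constant features get importance 0 with a flag; trees whose OOB
sample lacks a class are skipped. Note that classical permutation
importance of a truly irrelevant variable is slightly positive in finite
samples when trees overfit it; regularising leaves (larger
`min_samples_leaf`) removes this bias, which is how the null-variable
property is demonstrated in the test suite.

## Synthetic cohort generator

The generator emulates the *margins and dependence structure* of a
suspected-infection ED cohort, not any real cohort's joint distribution.
Defaults: 886 presentations; 330/886 incomplete vital panels; 54 % latent
sepsis prevalence; 10.3 % ICU admission and 23.7 % 28-day mortality;
bilirubin missing in 87 % of panels; PaO₂ present in 15 %.

One latent severity per patient (Normal(0, 0.8), shifted by +1.8 in the
latent sepsis group) drives all vitals through monotone links (tachypnea,
tachycardia, hypotension, fever, hypoxemia, supplemental oxygen, altered
mentation) with truncation to physiologic ranges. Organ-dysfunction labs
are drawn conditional on the latent label: a sepsis patient receives a
primary dysfunctional organ (renal 0.45 / coagulation 0.30 / cardiovascular
0.25) at SOFA 2 intensity plus an occasional mild secondary component;
non-sepsis patients get normal-range labs with a 12 % chance of one
borderline component. This makes downstream Sepsis-3 adjudication agree
with the latent assignment for ≥ 95 % of complete records — the remaining
discordance comes from chronic-code masking (per-organ prevalences 1–5 %)
and borderline vitals, which is the realistic direction of error.

Outcome intercepts are calibrated by bisection on the realized severity
draw so the configured ICU/mortality rates hold in expectation; outcome
noise is then binomial. Incomplete patients are drawn as an *exact count*
(round(p·n) positions chosen at random), so the completeness-flow
arithmetic (556/886 = 63 %) is deterministic; which fields are blanked
follows configurable per-field weights (temperature and mentation most
often, as in practice), missing-completely-at-random by default with an
optional severity-dependent missingness slope for sensitivity analyses.
Empirical margins are verified in tests against ~3σ binomial bounds (a
fixed-seed run is a single binomial draw; 95 % bounds would false-alarm on
one margin in twenty).

What passing tests on this generator do **not** show: performance on real
cohorts with measurement error, informative missingness, correlated
comorbidity coding, or time-varying vitals. The generator exists so the
pipeline's logic and statistics are exercised end to end, with score–outcome
correlations of realistic sign and order.

## Problem sizes and determinism

Tests and the acceptance script run cohorts of 886 (the default), forests
of 25–200 trees with 3–20 permutation repetitions, 2000-replicate
bootstraps, and 10,000-replicate coverage simulations — sizes chosen so the
full suite completes in well under a minute of forest time while leaving
Monte-Carlo error far below the tolerances asserted. Every stochastic step
(cohort generation, bootstrap, permutation, forest fitting) takes an
explicit seed; identical config + seed reproduces byte-identical cohort
CSVs and report JSON.

## Known limitations

- Respiratory SOFA ignores ventilation mode (the 3–4 levels normally
  require respiratory support); ED extracts rarely record it.
- Cardiovascular SOFA cannot exceed 2 without vasopressor dose rates.
- The chronic/acute word test operates on the shipped label lexicon; real
  deployments should key it to their local ICD-10 catalogue (the organ
  prefix map is language-independent, the labels are not).
- Fixed-time scoring only: no worst-in-48h windows or time-series SOFA.
- NEWS2, MEWS, SIRS and pediatric scoring are out of scope.
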