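# sepscreen

Early-warning-score sepsis screening analysis for emergency-department (ED)
cohorts: bit-exact **NEWS**, **qSOFA** and **SOFA** calculators with
chart-review conventions, **Sepsis-3** adjudication, a diagnostic-accuracy
engine with exact binomial confidence intervals and ROC/AUC, conditional
permutation importance for random-forest models, and a seeded synthetic
cohort generator so the whole pipeline runs and is tested without any
patient data.

## The problem

Screening ED patients for sepsis trades sensitivity against specificity.
qSOFA (one point each for respiratory rate ≥ 22 /min, systolic BP
≤ 100 mmHg, altered mentation; positive at ≥ 2) is simple and specific but
misses many septic patients. The National Early Warning Score (2012 chart;
seven vital-sign components banded to 0–3 points, positive at ≥ 5) is more
sensitive. Comparing them fairly requires a reference standard — Sepsis-3:
suspected infection plus an acute SOFA rise of ≥ 2 points — computed from
retrospective data with explicit conventions for what charts do not record:

- **missing bilirubin** is assumed normal (< 20 µmol/L), flagged `imputed`;
- **missing PaO₂** routes the respiratory SOFA component through the
  SpO₂/FiO₂ ratio (S/F 315 ↔ P/F 300, S/F 235 ↔ P/F 200, linear extension,
  valid for SpO₂ ≤ 97 %);
- **chronic organ dysfunction** must not count as an acute rise: ICD-10
  discharge codes whose labels read *chronic* without *acute* mask the
  matching SOFA organ (circulation `I`, coagulation `D65`–`D69`, renal
  `N0`–`N3`, liver `K7`, nervous `G`, respiration `J`);
- **GCS → AVPU** conversion (15→A, 13–14→V, 9–12→P, 3–8→U) resolves
  mentation for NEWS when only a GCS was charted.

For each score × endpoint (sepsis, ICU admission, 28-day mortality) the
package reports sensitivity, specificity, PPV, NPV and accuracy with
Clopper–Pearson exact 95 % intervals (the interval for k successes of n is
`[Beta⁻¹(α/2; k, n−k+1), Beta⁻¹(1−α/2; k+1, n−k)]`), ROC curves whose
trapezoidal AUC equals the tie-corrected Mann–Whitney statistic
U/(n₊·n₋), and DeLong or stratified-bootstrap AUC intervals. Variable
importance is the Strobl-style conditional permutation importance: the mean
decrease in out-of-bag AUC when a vital is permuted within strata of its
correlated covariates.

## Worked example

```python
import sepscreen as ss

vitals = ss.VitalSet(respiratory_rate=22, systolic_bp=100, spo2=96,
                     supplemental_o2=False, temperature=37.0,
                     heart_rate=70, gcs=15)
ss.compute_news(vitals).total    # -> 4
ss.compute_qsofa(vitals).total   # -> 2
```

This is the boundary patient: qSOFA-positive (2) yet below the NEWS ≥ 5
alert threshold — NEWS 4 = 2 points for SBP in the 91–100 band + 2 points
for RR in the 21–24 band. Running `python examples/01_score_a_patient.py`
prints:

```
NEWS  = 4  components: {'respiratory_rate': 2, 'spo2': 0, 'supplemental_o2': 0, 'temperature': 0, 'systolic_bp': 2, 'heart_rate': 0, 'avpu': 0}
qSOFA = 2  components: {'respiratory_rate': 1, 'systolic_bp': 1, 'mentation': 0}
SOFA  = 4  (coagulation 2, renal 2; liver provenance: imputed)
Sepsis-3 positive (SOFA >= 2): True
```

Reconstructing an accuracy table from printed summaries (sensitivity 0.86,
specificity 0.55, 300 sepsis / 256 non-sepsis):

```python
cm = ss.reconstruct_confusion(0.86, 0.55, 300, 256)   # tp=258 fn=42 tn=141 fp=115
m = ss.metrics(cm)
m["ppv"].percent, m["npv"].percent, m["accuracy"].percent   # -> (69, 77, 72)
ss.clopper_pearson(258, 300)   # -> (0.8155, 0.8972), i.e. 86% (95% CI 82-90%)
```

The `examples/` directory holds one short script per capability (scoring,
cohort adjudication, accuracy-table reconstruction, ROC/AUC, variable
importance); each prints the numbers it computes and a line on what they
mean. The same stages are available from a shell:

```bash
sepscreen run --seed 1 --out results/ --reproduce-table1
sepscreen generate --seed 1 --out cohort.csv     # or stage by stage
sepscreen adjudicate --cohort cohort.csv --out adjudicated.csv
```

Band tables (NEWS bands, SOFA thresholds, S/F equivalence, GCS→AVPU map)
ship as versioned YAML verified by checksum; pass `--allow-custom-bands` to
use a deliberately customised chart.

## Layout

- `src/sepscreen/scores.py` — NEWS / qSOFA / SOFA calculators, GCS→AVPU
- `src/sepscreen/adjudication.py` — completeness filter, imputation, ICD-10 masking, Sepsis-3 labels
- `src/sepscreen/diagnostics.py` — confusion matrices, exact CIs, ROC/AUC, table reconstruction
- `src/sepscreen/importance.py` — random forest + conditional permutation importance
- `src/sepscreen/synthetic.py` — latent-severity synthetic ED cohort generator
- `src/sepscreen/pipeline.py`, `cli.py` — orchestration, reports, thin CLI
- `docs/methods.md` — model, assumptions, defaults and limitations
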