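"""Score a single ED presentation: NEWS, qSOFA and SOFA with provenance.

The patient below is the classic boundary case: systolic BP 100 mmHg and
respiratory rate 22 /min sit exactly on the qSOFA criteria (score 2, i.e.
"positive") while NEWS reaches only 4 — one point short of the >= 5 alert
threshold used for sepsis screening.
"""

import sepscreen as ss

vitals = ss.VitalSet(
    respiratory_rate=22, systolic_bp=100, spo2=96, supplemental_o2=False,
    temperature=37.0, heart_rate=70, gcs=15,
)

news = ss.compute_news(vitals)
qsofa = ss.compute_qsofa(vitals)
print(f"NEWS  = {news.total}  components: {news.components}")
print(f"qSOFA = {qsofa.total}  components: {qsofa.components}")

# SOFA from a partial lab panel: bilirubin was never drawn (imputed normal)
# and there is no blood gas, so respiration is scored from SpO2/FiO2.
labs = ss.impute_labs(ss.LabPanel(platelets=90, map=88, vasopressor=False,
                                  creatinine=185))
sofa = ss.compute_sofa(labs, vitals)
print(f"SOFA  = {sofa.total}  "
      f"(coagulation {sofa.coagulation}, renal {sofa.renal}; "
      f"liver provenance: {sofa.provenance['liver'].value})")
print("Sepsis-3 positive (SOFA >= 2):", sofa.total >= 2)
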