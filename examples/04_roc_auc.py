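"""ROC curves and AUC confidence intervals for NEWS and qSOFA.

On a synthetic cohort, both scores are swept over all observed cut-offs
against the sepsis endpoint; the trapezoidal AUC (identical to the
tie-corrected Mann-Whitney statistic) is reported with a DeLong 95% CI.
An AUC of 0.5 is chance; 1.0 is perfect discrimination.
"""

import sepscreen as ss
from sepscreen.pipeline import score_cohort
from sepscreen.synthetic import CohortConfig

records = ss.generate(CohortConfig(seed=1))
complete, _ = ss.filter_complete(records)
scored = score_cohort(complete)
y = scored["sepsis"].to_numpy(dtype=bool)

for name in ("news", "qsofa"):
    curve = ss.roc_with_ci(scored[name].to_numpy(dtype=float), y,
                           endpoint="sepsis", score_name=name, seed=1)
    print(f"{name.upper():5s} AUC {curve.auc:.3f} "
          f"(95% CI {curve.auc_ci_low:.3f}-{curve.auc_ci_high:.3f}, "
          f"{curve.ci_method}) over {len(curve.thresholds)} thresholds")

m5 = ss.metrics(ss.confusion(y, scored["news"].to_numpy() >= 5))
m4 = ss.metrics(ss.confusion(y, scored["news"].to_numpy() >= 4))
print(f"NEWS>=5 sensitivity {m5['sensitivity'].percent}% vs "
      f"NEWS>=4 sensitivity {m4['sensitivity'].percent}% "
      "(lowering the cut-off can only gain sensitivity)")
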