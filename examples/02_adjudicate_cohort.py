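"""Generate a synthetic suspected-infection cohort and adjudicate it.

Reproduces the study-flow arithmetic: of the presentations with a suspected
infection, those lacking any vital sign needed for NEWS/qSOFA are excluded,
and the remainder are labelled by the Sepsis-3 rule (SOFA >= 2 after
imputation and chronic-disease masking).
"""

import sepscreen as ss
from sepscreen.pipeline import score_cohort
from sepscreen.synthetic import CohortConfig

records = ss.generate(CohortConfig(seed=1))
complete, excluded = ss.filter_complete(records)
scored = score_cohort(complete)

n = len(records)
print(f"suspected infection : {n}")
print(f"complete vitals     : {len(complete)} ({100 * len(complete) / n:.0f}%)")
print(f"excluded            : {len(excluded)}")
print(f"sepsis (Sepsis-3)   : {scored['sepsis'].sum()} "
      f"({100 * scored['sepsis'].mean():.1f}% of complete)")
print(f"ICU admission       : {100 * scored['icu'].mean():.1f}%")
print(f"28-day mortality    : {100 * scored['mortality'].mean():.1f}%")
print(f"organ masks applied : {scored[[c for c in scored if c.startswith('mask_')]].any(axis=1).sum()} patients")
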