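# sepscreen score band tables, version 1.
#
# NEWS bands are the 2012 Royal College of Physicians chart (not NEWS2):
# each numeric parameter maps to points via inclusive [lo, hi] bands that
# partition the admissible range. Temperature is banded at one-decimal
# precision; inputs are rounded to one decimal before lookup.
version: 1
news:
  respiratory_rate:        # breaths/min, integer
    range: [0, 90]
    bands:
      - {lo: 0, hi: 8, points: 3}
      - {lo: 9, hi: 11, points: 1}
      - {lo: 12, hi: 20, points: 0}
      - {lo: 21, hi: 24, points: 2}
      - {lo: 25, hi: 90, points: 3}
  spo2:                    # %, integer
    range: [0, 100]
    bands:
      - {lo: 0, hi: 91, points: 3}
      - {lo: 92, hi: 93, points: 2}
      - {lo: 94, hi: 95, points: 1}
      - {lo: 96, hi: 100, points: 0}
  temperature:             # degrees C, one-decimal resolution
    range: [25.0, 45.0]
    resolution: 0.1
    bands:
      - {lo: 25.0, hi: 35.0, points: 3}
      - {lo: 35.1, hi: 36.0, points: 1}
      - {lo: 36.1, hi: 38.0, points: 0}
      - {lo: 38.1, hi: 39.0, points: 1}
      - {lo: 39.1, hi: 45.0, points: 2}
  systolic_bp:             # mmHg, integer
    range: [20, 300]
    bands:
      - {lo: 20, hi: 90, points: 3}
      - {lo: 91, hi: 100, points: 2}
      - {lo: 101, hi: 110, points: 1}
      - {lo: 111, hi: 219, points: 0}
      - {lo: 220, hi: 300, points: 3}
  heart_rate:              # beats/min, integer
    range: [0, 300]
    bands:
      - {lo: 0, hi: 40, points: 3}
      - {lo: 41, hi: 50, points: 1}
      - {lo: 51, hi: 90, points: 0}
      - {lo: 91, hi: 110, points: 1}
      - {lo: 111, hi: 130, points: 2}
      - {lo: 131, hi: 300, points: 3}
  supplemental_o2:         # any oxygen therapy scores 2
    "true": 2
    "false": 0
  avpu:                    # only Alert scores 0
    A: 0
    V: 3
    P: 3
    U: 3

qsofa:
  respiratory_rate_min: 22   # >= 22 /min scores 1
  systolic_bp_max: 100       # <= 100 mmHg scores 1
  # altered mentation (GCS < 15 or AVPU != A) scores 1

sofa:
  # "below" cuts: score = number of cuts the value falls below (descending).
  # "above" cuts + upper_inclusive: score = number of ascending cuts the value
  # reaches, with score 4 only strictly above upper_inclusive.
  respiration_pf:          # PaO2/FiO2 in mmHg: >=400 -> 0 ... <100 -> 4
    below: [400, 300, 200, 100]
  coagulation_platelets:   # 10^9/L: >=150 -> 0 ... <20 -> 4
    below: [150, 100, 50, 20]
  liver_bilirubin:         # umol/L: <20 -> 0, 20-32 -> 1, 33-101 -> 2, 102-204 -> 3, >204 -> 4
    above: [20, 33, 102]
    upper_inclusive: 204
  cardiovascular:
    map_min: 70            # MAP < 70 mmHg without vasopressor -> 1
    vasopressor_score: 2   # any vasopressor -> 2 (dose rates not available)
  cns_gcs:                 # 15 -> 0, 13-14 -> 1, 10-12 -> 2, 6-9 -> 3, 3-5 -> 4
    below: [15, 13, 10, 6]
  renal_creatinine:        # umol/L: <110 -> 0, 110-170 -> 1, 171-299 -> 2, 300-440 -> 3, >440 -> 4
    above: [110, 171, 300]
    upper_inclusive: 440

# SpO2/FiO2 fallback for respiratory SOFA when PaO2 is unavailable.
# Anchored at S/F 315 <-> P/F 300 and S/F 235 <-> P/F 200; the 400 and 100
# P/F cut-offs are linear extensions of that line (S/F = 0.8*P/F + 75).
# Valid for SpO2 <= spo2_validity_max; above it on room air the component
# is 0, on supplemental oxygen SpO2 is capped at the ceiling first.
sf_equivalence:
  spo2_validity_max: 97
  below: [395, 315, 235, 155]   # S/F below cut -> at least that score

# GCS -> AVPU conversion: lowest GCS mapping to each level.
gcs_to_avpu:
  A: 15
  V: 13
  P: 9
  U: 3
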