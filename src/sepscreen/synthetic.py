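"""Seeded synthetic ED cohort generator.

Emulates a suspected-infection emergency-department cohort with the margins
the analysis assumes: ~886 presentations of which ~37% lack at least one
vital sign, ~54% sepsis prevalence among complete records, ~10.3% ICU
admission and ~23.7% 28-day mortality, and bilirubin missing in 87% of
panels. The generative model is latent-severity based: one scalar severity
per patient (shifted upward in the latent sepsis group) drives vitals, labs
and outcomes through monotone links, which induces the score-outcome
correlations the analysis assumes without modelling any real cohort's joint
distribution.

Organ-dysfunction labs are drawn conditional on the latent sepsis
assignment (a "primary" dysfunctional organ scoring 2 SOFA points, plus
occasional mild secondary components), so downstream Sepsis-3 adjudication
agrees with the latent label for >= 95% of complete records; chronic-disease
codes and borderline vitals account for the remaining discordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .types import Avpu, Icd10Code, LabPanel, PaO2Unit, PatientRecord, ValidationError, VitalSet

DEFAULT_EFFECTS = {
    "severity_shift": 1.8,   # latent-severity separation, sepsis vs not
    "respiratory_rate": 3.2,  # slope per severity unit
    "heart_rate": 9.0,
    "systolic_bp": 11.0,      # subtracted (hypotension)
    "temperature": 0.5,
    "spo2": 1.6,              # subtracted (hypoxemia)
}

DEFAULT_MISSINGNESS = {
    "temperature": 0.45,
    "mentation": 0.35,
    "respiratory_rate": 0.30,
    "spo2": 0.20,
    "systolic_bp": 0.15,
    "heart_rate": 0.15,
    "supplemental_o2": 0.10,
}

DEFAULT_CHRONIC_PREVALENCE = {
    "cardiovascular": 0.05,
    "respiration": 0.05,
    "renal": 0.04,
    "cns": 0.02,
    "liver": 0.02,
    "coagulation": 0.01,
}

# small chronic-disease lexicon: organ -> (ICD-10 code, label)
CHRONIC_LEXICON = {
    "cardiovascular": ("I50.1", "chronic left ventricular failure"),
    "respiration": ("J44.9", "chronic obstructive pulmonary disease"),
    "renal": ("N18.3", "chronic kidney disease, stage 3"),
    "cns": ("G35", "multiple sclerosis, chronic progressive"),
    "liver": ("K74.6", "chronic cirrhosis of liver"),
    "coagulation": ("D68.9", "chronic coagulation defect"),
}

# distractor codes: no organ prefix match, or chronic-with-acute labels
DISTRACTOR_CODES = (
    ("E11.9", "type 2 diabetes mellitus"),
    ("M54.5", "low back pain"),
    ("J44.1", "chronic obstructive pulmonary disease with acute exacerbation"),
    ("F03", "dementia"),
)


@dataclass(frozen=True)
class CohortConfig:
    """Margins and structure of the generated cohort."""

    n_total: int = 886
    p_incomplete: float = 330 / 886
    p_sepsis_given_complete: float = 0.54
    p_icu: float = 0.103
    p_mort28: float = 0.237
    p_bilirubin_missing: float = 0.87
    p_pao2_present: float = 0.15
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    missingness_pattern: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    p_chronic_codes: dict = field(default_factory=lambda: dict(DEFAULT_CHRONIC_PREVALENCE))
    severity_dependent_missingness: float = 0.0   # optional logit slope on severity
    seed: int = 0

    def __post_init__(self):
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        for name in ("p_incomplete", "p_sepsis_given_complete", "p_icu",
                     "p_mort28", "p_bilirubin_missing", "p_pao2_present"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} must be a proportion in [0, 1]")
        for name, prob in {**self.missingness_pattern, **self.p_chronic_codes}.items():
            if not (0.0 <= prob <= 1.0):
                raise ValidationError(f"probability for {name!r} must be in [0, 1]")

    def null_effects(self) -> "CohortConfig":
        """Copy with all group effects removed (no-signal null)."""
        return replace(self, effect_sizes={k: 0.0 for k in self.effect_sizes})


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(severity: np.ndarray, slope: float, target: float) -> float:
    """Intercept a such that mean sigmoid(a + slope*sev) == target (bisection)."""
    if target <= 0.0:
        return -math.inf
    if target >= 1.0:
        return math.inf
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if _sigmoid(mid + slope * severity).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _draw_vitals(rng: np.random.Generator, sev: float, es: dict) -> dict:
    def clip(v, lo, hi):
        return min(max(v, lo), hi)

    rr = int(round(clip(rng.normal(16 + es["respiratory_rate"] * sev, 3.0), 8, 55)))
    hr = int(round(clip(rng.normal(82 + es["heart_rate"] * sev, 11.0), 35, 175)))
    sbp = int(round(clip(rng.normal(127 - es["systolic_bp"] * sev, 16.0), 55, 230)))
    temp = round(clip(rng.normal(36.9 + es["temperature"] * sev, 0.55), 34.0, 41.5), 1)
    spo2 = int(round(clip(rng.normal(96.8 - es["spo2"] * sev, 1.8), 70, 100)))
    on_o2 = bool(rng.random() < _sigmoid(-2.8 + 0.9 * sev))
    fio2 = float(rng.choice([0.24, 0.28, 0.32, 0.40, 0.50],
                            p=[0.35, 0.25, 0.2, 0.12, 0.08])) if on_o2 else 0.21
    altered = rng.random() < _sigmoid(-3.0 + 1.1 * sev)
    if altered:
        deficit = 1 + (rng.poisson(1.2) if sev > 0.8 else 0)
        gcs = max(3, 15 - deficit)
    else:
        gcs = 15
    return dict(respiratory_rate=rr, heart_rate=hr, systolic_bp=sbp,
                temperature=temp, spo2=spo2, supplemental_o2=on_o2,
                fio2=fio2, gcs=gcs)


def _draw_labs(rng: np.random.Generator, sev: float, sepsis: bool, cfg: CohortConfig,
               fio2: float) -> LabPanel:
    def clip(v, lo, hi):
        return min(max(v, lo), hi)

    creat = clip(rng.normal(82 + 6 * max(sev, 0), 18), 30, 168)
    platelets = clip(rng.normal(250 - 15 * max(sev, 0), 70), 110, 600)
    mean_ap = clip(rng.normal(92 - 7 * sev, 10), 70, 130)
    vasopressor = False
    if sepsis:
        primary = rng.choice(["renal", "coagulation", "cardiovascular"], p=[0.45, 0.30, 0.25])
        if primary == "renal":
            creat = rng.uniform(180, 420)
        elif primary == "coagulation":
            platelets = rng.uniform(30, 95)
        else:
            vasopressor = True
            mean_ap = rng.uniform(45, 68)
        if rng.random() < 0.5:   # mild secondary dysfunction
            secondary = rng.choice(["renal", "coagulation", "cardiovascular"])
            if secondary != primary:
                if secondary == "renal":
                    creat = rng.uniform(115, 165)
                elif secondary == "coagulation":
                    platelets = rng.uniform(105, 145)
                else:
                    mean_ap = rng.uniform(60, 69)
    elif rng.random() < 0.12:    # borderline single component in non-sepsis
        which = rng.choice(["renal", "coagulation", "cardiovascular"])
        if which == "renal":
            creat = rng.uniform(112, 150)
        elif which == "coagulation":
            platelets = rng.uniform(105, 145)
        else:
            mean_ap = rng.uniform(62, 69)

    bilirubin = None
    if rng.random() >= cfg.p_bilirubin_missing:
        if sepsis:
            bilirubin = clip(rng.normal(20, 12), 3, 120)
        else:
            bilirubin = clip(rng.normal(12, 6), 2, 32)

    pao2 = None
    unit = PaO2Unit.MMHG
    if rng.random() < cfg.p_pao2_present:
        pao2 = clip(rng.normal(95 - 8 * sev, 12), 40, 130)
        if rng.random() < 0.3:
            pao2 = round(pao2 / 7.50062, 2)
            unit = PaO2Unit.KPA
        else:
            pao2 = round(pao2, 1)

    return LabPanel(
        pao2=pao2, pao2_unit=unit, fio2=fio2,
        platelets=round(platelets), bilirubin=None if bilirubin is None else round(bilirubin, 1),
        map=round(mean_ap), vasopressor=vasopressor, creatinine=round(creat),
    )


def _draw_codes(rng: np.random.Generator, cfg: CohortConfig) -> list[Icd10Code]:
    codes = [Icd10Code(*CHRONIC_LEXICON[organ])
             for organ, p in cfg.p_chronic_codes.items() if rng.random() < p]
    if rng.random() < 0.3:
        codes.append(Icd10Code(*DISTRACTOR_CODES[rng.integers(len(DISTRACTOR_CODES))]))
    return codes


_MENTATION_FIELDS = {"mentation": ("gcs", "avpu"), "supplemental_o2": ("supplemental_o2", "fio2")}


def _apply_missingness(rng: np.random.Generator, vit: dict, pattern: dict) -> dict:
    """Blank fields per the missingness pattern, forcing at least one gap."""
    names = list(pattern)
    probs = np.array([pattern[n] for n in names], dtype=float)
    drop = [n for n in names if rng.random() < pattern[n]]
    if not drop:
        drop = [str(rng.choice(names, p=probs / probs.sum()))]
    out = dict(vit)
    for name in drop:
        for f in _MENTATION_FIELDS.get(name, (name,)):
            out[f] = None
    return out


def generate_with_truth(config: Optional[CohortConfig] = None
                        ) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a cohort plus a truth table (latent sepsis, severity, flags)."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    es = cfg.effect_sizes

    sepsis = rng.random(n) < cfg.p_sepsis_given_complete
    shift = es.get("severity_shift", 0.0)
    severity = rng.normal(0.0, 0.8, n) + shift * sepsis

    # outcomes: logistic in severity, intercept calibrated to the target margin
    a_icu = _calibrate_intercept(severity, 1.3, cfg.p_icu)
    a_mort = _calibrate_intercept(severity, 1.5, cfg.p_mort28)
    icu = rng.random(n) < _sigmoid(a_icu + 1.3 * severity)
    mort = rng.random(n) < _sigmoid(a_mort + 1.5 * severity)

    # exact incomplete count at random positions (deterministic flow accounting)
    n_incomplete = round(cfg.p_incomplete * n)
    incomplete_idx = set(rng.choice(n, size=n_incomplete, replace=False).tolist())

    records = []
    truth_rows = []
    for i in range(n):
        sev = float(severity[i])
        vit = _draw_vitals(rng, sev, es)
        labs = _draw_labs(rng, sev, bool(sepsis[i]), cfg, vit["fio2"])
        codes = _draw_codes(rng, cfg)

        gcs = vit.pop("gcs")
        avpu = None
        u = rng.random()
        if u < 0.5:            # both recorded
            vit["gcs"], avpu = gcs, Avpu.A if gcs >= 15 else None
        elif u < 0.8:          # GCS only
            vit["gcs"] = gcs
        else:                  # AVPU only
            from .scores import gcs_to_avpu
            avpu = gcs_to_avpu(gcs)
        if avpu is None and "gcs" in vit and vit["gcs"] is not None and u < 0.5:
            from .scores import gcs_to_avpu
            avpu = gcs_to_avpu(vit["gcs"])
        vit["avpu"] = avpu
        if vit.get("fio2") == 0.21 and not vit["supplemental_o2"]:
            vit["fio2"] = None   # room air: no measured FiO2 in the chart

        if i in incomplete_idx:
            vit = _apply_missingness(rng, vit, cfg.missingness_pattern)

        records.append(PatientRecord(
            id=f"P{i:04d}",
            vitals=VitalSet(**vit),
            labs=labs,
            icd10_codes=tuple(codes),
            suspected_infection=True,
            icu_admission=bool(icu[i]),
            death_28d=bool(mort[i]),
        ))
        truth_rows.append({"id": f"P{i:04d}", "sepsis_latent": bool(sepsis[i]),
                           "severity": sev, "incomplete": i in incomplete_idx})
    return records, pd.DataFrame(truth_rows)


def generate(config: Optional[CohortConfig] = None) -> list[PatientRecord]:
    """Generate a reproducible synthetic suspected-infection ED cohort."""
    return generate_with_truth(config)[0]


_NORMAL_LABS = LabPanel(pao2=95.0, pao2_unit=PaO2Unit.MMHG, fio2=0.21,
                        platelets=250, bilirubin=10.0, map=90, vasopressor=False,
                        creatinine=80)

_ZERO_BAND = dict(respiratory_rate=16, spo2=98, supplemental_o2=False,
                  temperature=37.0, systolic_bp=120, heart_rate=70,
                  gcs=15, avpu=Avpu.A)


def _fixture(name: str, **vital_overrides) -> PatientRecord:
    vit = {**_ZERO_BAND, **vital_overrides}
    return PatientRecord(id=name, vitals=VitalSet(**vit), labs=_NORMAL_LABS)


def generate_worked_examples() -> list[PatientRecord]:
    """Fixed fixture records: the NEWS-4/qSOFA-2 boundary patient, an
    all-normal patient, and both edges of every band of every NEWS component.
    """
    from .bands import default_bands

    bands = default_bands()
    fixtures = [
        _fixture("boundary_news4", systolic_bp=100, respiratory_rate=22, spo2=96),
        _fixture("all_normal"),
    ]
    for param in ("respiratory_rate", "spo2", "temperature", "systolic_bp", "heart_rate"):
        for band in bands.news[param]["bands"]:
            for edge in ("lo", "hi"):
                value = band[edge]
                name = f"edge_{param}_{value}"
                fixtures.append(_fixture(name, **{param: value}))
    fixtures.append(_fixture("edge_supplemental_o2_true", supplemental_o2=True, fio2=0.28))
    for level in (Avpu.A, Avpu.V, Avpu.P, Avpu.U):
        fixtures.append(_fixture(f"edge_avpu_{level.name}", avpu=level,
                                 gcs=None))
    return fixtures
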