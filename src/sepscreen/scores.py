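"""NEWS, qSOFA and SOFA calculators.

NEWS is the 2012 Royal College of Physicians National Early Warning Score:
seven vital-sign components (respiratory rate, SpO2, supplemental oxygen,
temperature, systolic blood pressure, heart rate, AVPU mental state), each
banded to 0-3 points (supplemental oxygen: 0 or 2), total 0-20. qSOFA scores
one point each for respiratory rate >= 22 /min, systolic BP <= 100 mmHg and
altered mentation. SOFA has six organ components scored 0-4 from labs and
GCS; here it is computed with the cohort pipeline's conventions: bilirubin
may be imputed as normal, respiration may fall back to the SpO2/FiO2 ratio
when no blood gas is available, and chronic-disease organ masking forces a
component to zero.
"""

from __future__ import annotations

from typing import Optional

from .bands import BandConfig, default_bands
from .types import (
    Avpu,
    IncompleteLabsError,
    IncompleteVitalsError,
    LabPanel,
    NewsScore,
    OrganMask,
    Provenance,
    QsofaScore,
    ScorePanel,
    SofaBreakdown,
    ValidationError,
    VitalSet,
    SOFA_ORGANS,
)


def gcs_to_avpu(gcs: int, bands: Optional[BandConfig] = None) -> Avpu:
    """Convert a Glasgow Coma Scale value to the AVPU scale.

    Default mapping: 15 -> A, 13-14 -> V, 9-12 -> P, 3-8 -> U (monotone;
    configurable through the band tables).
    """
    if not isinstance(gcs, int) or isinstance(gcs, bool) or not (3 <= gcs <= 15):
        raise ValidationError(f"gcs={gcs!r} outside [3, 15]")
    table = (bands or default_bands()).gcs_to_avpu
    for level in (Avpu.A, Avpu.V, Avpu.P, Avpu.U):
        if gcs >= table[level]:
            return level
    raise AssertionError("unreachable: U maps from GCS 3")


def _resolve_avpu(vitals: VitalSet, bands: BandConfig) -> Optional[Avpu]:
    if vitals.avpu is not None:
        return vitals.avpu
    if vitals.gcs is not None:
        return gcs_to_avpu(vitals.gcs, bands)
    return None


def missing_news_inputs(vitals: VitalSet, bands: Optional[BandConfig] = None) -> list[str]:
    """Names of NEWS inputs that cannot be resolved from this vital set."""
    bands = bands or default_bands()
    missing = [
        name
        for name in ("respiratory_rate", "spo2", "supplemental_o2", "temperature",
                     "systolic_bp", "heart_rate")
        if getattr(vitals, name) is None
    ]
    if _resolve_avpu(vitals, bands) is None:
        missing.append("avpu")
    return missing


def compute_news(vitals: VitalSet, bands: Optional[BandConfig] = None) -> NewsScore:
    """Compute the NEWS total and its seven component points."""
    bands = bands or default_bands()
    missing = missing_news_inputs(vitals, bands)
    if missing:
        raise IncompleteVitalsError(missing)
    avpu = _resolve_avpu(vitals, bands)
    components = {
        "respiratory_rate": bands.news_points("respiratory_rate", vitals.respiratory_rate),
        "spo2": bands.news_points("spo2", vitals.spo2),
        "supplemental_o2": bands.news["supplemental_o2"]["true" if vitals.supplemental_o2 else "false"],
        "temperature": bands.news_points("temperature", vitals.temperature),
        "systolic_bp": bands.news_points("systolic_bp", vitals.systolic_bp),
        "heart_rate": bands.news_points("heart_rate", vitals.heart_rate),
        "avpu": bands.news["avpu"][avpu.name],
    }
    return NewsScore(components=components, total=sum(components.values()))


def compute_qsofa(vitals: VitalSet, bands: Optional[BandConfig] = None) -> QsofaScore:
    """Compute qSOFA: RR >= 22, SBP <= 100, altered mentation (GCS < 15 or not Alert)."""
    bands = bands or default_bands()
    missing = [n for n in ("respiratory_rate", "systolic_bp") if getattr(vitals, n) is None]
    if not vitals.has_mentation():
        missing.append("mentation")
    if missing:
        raise IncompleteVitalsError(missing)
    if vitals.gcs is not None:
        altered = vitals.gcs < 15
    else:
        altered = vitals.avpu is not Avpu.A
    components = {
        "respiratory_rate": int(vitals.respiratory_rate >= bands.qsofa["respiratory_rate_min"]),
        "systolic_bp": int(vitals.systolic_bp <= bands.qsofa["systolic_bp_max"]),
        "mentation": int(altered),
    }
    return QsofaScore(components=components, total=sum(components.values()))


def compute_panel(vitals: VitalSet, bands: Optional[BandConfig] = None) -> ScorePanel:
    """NEWS and qSOFA from the same vital-sign set."""
    bands = bands or default_bands()
    return ScorePanel(news=compute_news(vitals, bands), qsofa=compute_qsofa(vitals, bands))


def _score_below(value: float, cuts: list) -> int:
    return sum(value < c for c in cuts)


def _score_above(value: float, cuts: list, upper_inclusive: float) -> int:
    if value > upper_inclusive:
        return 4
    return sum(value >= c for c in cuts)


def sofa_respiratory_from_spo2(spo2: float, fio2: float,
                               bands: Optional[BandConfig] = None) -> int:
    """Respiratory SOFA component from the SpO2/FiO2 ratio.

    Stand-in for the PaO2/FiO2 ratio when no arterial blood gas exists. The
    default equivalence anchors S/F 315 at P/F 300 and S/F 235 at P/F 200,
    extended linearly to the 400 and 100 cut-offs. The linear relation is
    only valid while the oximeter is off its ceiling: above the validity
    maximum (97%) a room-air patient scores 0, and on supplemental oxygen
    SpO2 is capped at the ceiling before the ratio is formed.
    """
    bands = bands or default_bands()
    if not (0 < spo2 <= 100):
        raise ValidationError(f"spo2={spo2} outside (0, 100]")
    if not (0.21 <= fio2 <= 1.0):
        raise ValidationError(f"fio2={fio2} outside [0.21, 1.0]")
    ceiling = bands.sf_equivalence["spo2_validity_max"]
    if spo2 > ceiling:
        if fio2 <= 0.21:
            return 0
        spo2 = ceiling
    return _score_below(spo2 / fio2, bands.sf_equivalence["below"])


def _respiration(labs: LabPanel, vitals: VitalSet, bands: BandConfig) -> tuple[int, Provenance]:
    fio2 = labs.fio2 if labs.fio2 is not None else vitals.fio2
    if fio2 is None and vitals.supplemental_o2 is False:
        fio2 = 0.21
    pao2 = labs.pao2_mmhg
    if pao2 is not None and fio2 is not None:
        return _score_below(pao2 / fio2, bands.sofa["respiration_pf"]["below"]), Provenance.MEASURED
    if vitals.spo2 is not None and fio2 is not None:
        return sofa_respiratory_from_spo2(vitals.spo2, fio2, bands), Provenance.IMPUTED
    raise IncompleteLabsError("respiration")


def _cardiovascular(labs: LabPanel, bands: BandConfig) -> int:
    cv = bands.sofa["cardiovascular"]
    if labs.vasopressor:
        return cv["vasopressor_score"]
    if labs.map is None:
        raise IncompleteLabsError("cardiovascular")
    return 1 if labs.map < cv["map_min"] else 0


def _cns_gcs(vitals: VitalSet, bands: BandConfig) -> int:
    gcs = vitals.gcs
    if gcs is None and vitals.avpu is not None:
        # invert the AVPU map at each level's upper GCS bound
        table = bands.gcs_to_avpu
        order = [Avpu.A, Avpu.V, Avpu.P, Avpu.U]
        idx = order.index(vitals.avpu)
        gcs = 15 if idx == 0 else table[order[idx - 1]] - 1
    if gcs is None:
        raise IncompleteLabsError("cns")
    return _score_below(gcs, bands.sofa["cns_gcs"]["below"])


def compute_sofa(labs: LabPanel, vitals: VitalSet,
                 mask: OrganMask = frozenset(),
                 bands: Optional[BandConfig] = None) -> SofaBreakdown:
    """Six-component SOFA with provenance and chronic-disease masking.

    ``labs`` is expected to have been through :func:`sepscreen.adjudication.
    impute_labs`; components named in ``mask`` are forced to 0 with
    provenance "masked". A component that is unresolvable and not masked
    raises :class:`IncompleteLabsError`.
    """
    bands = bands or default_bands()
    bad = set(mask) - set(SOFA_ORGANS)
    if bad:
        raise ValidationError(f"unknown SOFA organs in mask: {sorted(bad)}")

    def resolve(organ: str, fn):
        if organ in mask:
            return 0, Provenance.MASKED
        value = fn()
        if isinstance(value, tuple):
            return value
        return value, Provenance.IMPUTED if organ in _imputed_organs else Provenance.MEASURED

    _imputed_organs = set()
    if "bilirubin" in labs.imputed:
        _imputed_organs.add("liver")

    def coagulation():
        if labs.platelets is None:
            raise IncompleteLabsError("coagulation")
        return _score_below(labs.platelets, bands.sofa["coagulation_platelets"]["below"])

    def liver():
        if labs.bilirubin is None:
            raise IncompleteLabsError("liver")
        spec = bands.sofa["liver_bilirubin"]
        return _score_above(labs.bilirubin, spec["above"], spec["upper_inclusive"])

    def renal():
        if labs.creatinine is None:
            raise IncompleteLabsError("renal")
        spec = bands.sofa["renal_creatinine"]
        return _score_above(labs.creatinine, spec["above"], spec["upper_inclusive"])

    scores = {}
    provenance = {}
    scores["respiration"], provenance["respiration"] = resolve(
        "respiration", lambda: _respiration(labs, vitals, bands))
    scores["coagulation"], provenance["coagulation"] = resolve("coagulation", coagulation)
    scores["liver"], provenance["liver"] = resolve("liver", liver)
    scores["cardiovascular"], provenance["cardiovascular"] = resolve(
        "cardiovascular", lambda: _cardiovascular(labs, bands))
    scores["cns"], provenance["cns"] = resolve("cns", lambda: _cns_gcs(vitals, bands))
    scores["renal"], provenance["renal"] = resolve("renal", renal)

    return SofaBreakdown(total=sum(scores.values()), provenance=provenance, **scores)
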