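"""Domain types for emergency-department sepsis screening.

All containers are plain dataclasses with eager validation: a value that is
present must be physiologically plausible, a value that is absent is ``None``.
Score calculators decide what "absent" means for them (e.g. mentation is
resolvable from either a GCS or an AVPU level).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class ValidationError(ValueError):
    """An input value is outside its physiologic/structural bounds."""


class IncompleteVitalsError(ValueError):
    """A score cannot be computed because a vital-sign input is missing."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"incomplete vitals: missing {', '.join(self.missing)}")


class IncompleteLabsError(ValueError):
    """A SOFA component is unresolvable after imputation and not masked."""

    def __init__(self, component: str):
        self.component = component
        super().__init__(f"incomplete labs: cannot resolve component '{component}'")


class Avpu(enum.IntEnum):
    """Alert / Verbal / Pain / Unresponsive mental-status scale (ordered)."""

    A = 0
    V = 1
    P = 2
    U = 3

    @classmethod
    def parse(cls, value: "str | Avpu") -> "Avpu":
        if isinstance(value, Avpu):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise ValidationError(f"invalid AVPU level: {value!r}") from None


# physiologic admissibility bounds (inclusive) for present vital values
_VITAL_BOUNDS = {
    "respiratory_rate": (0, 90),
    "spo2": (0, 100),
    "temperature": (25.0, 45.0),
    "systolic_bp": (20, 300),
    "heart_rate": (0, 300),
}


@dataclass(frozen=True)
class VitalSet:
    """One set of ED vital signs; any field may be missing (``None``).

    ``supplemental_o2`` is the NEWS oxygen-therapy flag; ``fio2`` is the
    inspired-oxygen fraction (0.21 on room air). An ``fio2`` above 0.21
    requires ``supplemental_o2`` to be true.
    """

    respiratory_rate: Optional[int] = None
    spo2: Optional[float] = None
    supplemental_o2: Optional[bool] = None
    fio2: Optional[float] = None
    temperature: Optional[float] = None
    systolic_bp: Optional[float] = None
    heart_rate: Optional[float] = None
    gcs: Optional[int] = None
    avpu: Optional[Avpu] = None

    def __post_init__(self):
        for name, (lo, hi) in _VITAL_BOUNDS.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.fio2 is not None:
            if not (0.21 <= self.fio2 <= 1.0):
                raise ValidationError(f"fio2={self.fio2} outside [0.21, 1.0]")
            if self.fio2 > 0.21 and self.supplemental_o2 is False:
                raise ValidationError(
                    f"fio2={self.fio2} > 0.21 requires supplemental_o2=True"
                )
        if self.gcs is not None and not (3 <= self.gcs <= 15):
            raise ValidationError(f"gcs={self.gcs} outside [3, 15]")
        if self.avpu is not None and not isinstance(self.avpu, Avpu):
            object.__setattr__(self, "avpu", Avpu.parse(self.avpu))

    def has_mentation(self) -> bool:
        return self.gcs is not None or self.avpu is not None


class PaO2Unit(str, enum.Enum):
    KPA = "kPa"
    MMHG = "mmHg"


KPA_TO_MMHG = 7.50062


@dataclass(frozen=True)
class LabPanel:
    """Laboratory panel relevant to SOFA; unit-tagged, no silent inference.

    ``imputed`` names fields whose values were filled by the cohort imputation
    rules rather than measured (tracked for score provenance).
    """

    pao2: Optional[float] = None
    pao2_unit: PaO2Unit = PaO2Unit.MMHG
    fio2: Optional[float] = None
    platelets: Optional[float] = None      # 10^9/L
    bilirubin: Optional[float] = None      # umol/L
    map: Optional[float] = None            # mmHg
    vasopressor: Optional[bool] = None
    creatinine: Optional[float] = None     # umol/L
    imputed: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not isinstance(self.pao2_unit, PaO2Unit):
            object.__setattr__(self, "pao2_unit", PaO2Unit(self.pao2_unit))
        for name in ("pao2", "fio2", "platelets", "bilirubin", "map", "creatinine"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name}={v} must be non-negative")
        if self.fio2 is not None and not (0.21 <= self.fio2 <= 1.0):
            raise ValidationError(f"fio2={self.fio2} outside [0.21, 1.0]")
        if not isinstance(self.imputed, frozenset):
            object.__setattr__(self, "imputed", frozenset(self.imputed))

    @property
    def pao2_mmhg(self) -> Optional[float]:
        if self.pao2 is None:
            return None
        if self.pao2_unit is PaO2Unit.KPA:
            return self.pao2 * KPA_TO_MMHG
        return self.pao2

    def with_imputed(self, **changes) -> "LabPanel":
        names = frozenset(self.imputed) | frozenset(changes)
        return replace(self, imputed=names, **changes)


NEWS_COMPONENTS = (
    "respiratory_rate",
    "spo2",
    "supplemental_o2",
    "temperature",
    "systolic_bp",
    "heart_rate",
    "avpu",
)

QSOFA_COMPONENTS = ("respiratory_rate", "systolic_bp", "mentation")


@dataclass(frozen=True)
class NewsScore:
    components: dict  # name -> points
    total: int

    def __post_init__(self):
        assert self.total == sum(self.components.values())
        assert 0 <= self.total <= 20


@dataclass(frozen=True)
class QsofaScore:
    components: dict  # name -> 0/1
    total: int

    def __post_init__(self):
        assert self.total == sum(self.components.values())
        assert 0 <= self.total <= 3


@dataclass(frozen=True)
class ScorePanel:
    """NEWS and qSOFA computed from the same vital-sign set."""

    news: NewsScore
    qsofa: QsofaScore


SOFA_ORGANS = (
    "respiration",
    "coagulation",
    "liver",
    "cardiovascular",
    "cns",
    "renal",
)


class Provenance(str, enum.Enum):
    MEASURED = "measured"
    IMPUTED = "imputed"
    MASKED = "masked"


@dataclass(frozen=True)
class SofaBreakdown:
    """Six organ-component SOFA scores, total, and per-component provenance."""

    respiration: int
    coagulation: int
    liver: int
    cardiovascular: int
    cns: int
    renal: int
    total: int
    provenance: dict  # organ -> Provenance

    def __post_init__(self):
        comps = [getattr(self, organ) for organ in SOFA_ORGANS]
        assert all(0 <= c <= 4 for c in comps)
        assert self.total == sum(comps)
        for organ in SOFA_ORGANS:
            if self.provenance[organ] is Provenance.MASKED:
                assert getattr(self, organ) == 0

    def component(self, organ: str) -> int:
        return getattr(self, organ)


@dataclass(frozen=True)
class Icd10Code:
    """ICD-10 discharge code plus its (free-text) label."""

    code: str
    label: str = ""


class SepsisLabel(str, enum.Enum):
    NO_SEPSIS = "no_sepsis"
    SEPSIS = "sepsis"


@dataclass(frozen=True)
class PatientRecord:
    """One ED presentation: vitals, labs, discharge codes and outcomes.

    Outcome fields are always present; vitals and labs may be incomplete.
    """

    id: str
    vitals: VitalSet
    labs: LabPanel
    icd10_codes: tuple = ()
    suspected_infection: bool = True
    icu_admission: bool = False
    death_28d: bool = False

    def __post_init__(self):
        object.__setattr__(self, "icd10_codes", tuple(self.icd10_codes))
        for c in self.icd10_codes:
            if not isinstance(c, Icd10Code):
                raise ValidationError(f"icd10_codes entries must be Icd10Code, got {c!r}")


OrganMask = frozenset  # subset of SOFA_ORGANS


def organ_mask(*organs: str) -> OrganMask:
    bad = set(organs) - set(SOFA_ORGANS)
    if bad:
        raise ValidationError(f"unknown SOFA organs in mask: {sorted(bad)}")
    return frozenset(organs)
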