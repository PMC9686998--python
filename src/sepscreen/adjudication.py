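"""Sepsis-3 electronic phenotyping for a suspected-infection ED cohort.

The pipeline mirrors retrospective chart-based adjudication: (1) keep only
presentations whose vital-sign panel suffices to compute both NEWS and
qSOFA; (2) impute missing labs with conservative rules (absent bilirubin is
taken as normal, an absent blood gas routes the respiratory component
through the SpO2/FiO2 fallback); (3) mask SOFA organ components explained by
a coded chronic disease, so the score measures an acute rise over the
patient's baseline; (4) label a complete suspected-infection presentation
as sepsis when the resulting SOFA total is >= 2.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Optional, Sequence

from .bands import BandConfig, default_bands
from .scores import compute_sofa, missing_news_inputs
from .types import (
    Icd10Code,
    LabPanel,
    OrganMask,
    PatientRecord,
    SepsisLabel,
    SofaBreakdown,
    ValidationError,
)

logger = logging.getLogger(__name__)

SEPSIS_SOFA_MIN = 2

#: ICD-10 code prefixes per SOFA organ system.
ORGAN_CODE_PREFIXES = {
    "cardiovascular": ("I",),
    "coagulation": ("D65", "D66", "D67", "D68", "D69"),
    "renal": ("N0", "N1", "N2", "N3"),
    "liver": ("K7",),
    "cns": ("G",),
    "respiration": ("J",),
}

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{1,4})?$")


def record_is_complete(record: PatientRecord, bands: Optional[BandConfig] = None) -> bool:
    """True iff every input needed for both NEWS and qSOFA is resolvable."""
    bands = bands or default_bands()
    # NEWS needs all seven components; qSOFA's inputs (RR, SBP, mentation)
    # are a subset, so NEWS completeness is the binding condition.
    return not missing_news_inputs(record.vitals, bands)


def filter_complete(cohort: Iterable[PatientRecord],
                    bands: Optional[BandConfig] = None
                    ) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Partition a cohort into (complete, excluded) by vital-sign completeness."""
    bands = bands or default_bands()
    complete, excluded = [], []
    for record in cohort:
        (complete if record_is_complete(record, bands) else excluded).append(record)
    return complete, excluded


#: Bilirubin sentinel for "assumed below the lowest scoring threshold" (umol/L).
BILIRUBIN_NORMAL_SENTINEL = 10.0


def impute_labs(labs: LabPanel) -> LabPanel:
    """Apply the cohort's lab imputation rules.

    Missing bilirubin is assumed normal (below the 20 umol/L scoring
    threshold) and flagged as imputed, so the liver component scores 0 with
    provenance "imputed". A missing PaO2 is left missing: the SOFA
    calculator then routes respiration through the SpO2/FiO2 equivalence.
    Other missing labs are left untouched.
    """
    if labs.bilirubin is None:
        return labs.with_imputed(bilirubin=BILIRUBIN_NORMAL_SENTINEL)
    return labs


def _label_is_chronic(label: str) -> bool:
    text = label.lower()
    return "chronic" in text and "acute" not in text


def chronic_mask(codes: Sequence[Icd10Code]) -> OrganMask:
    """Organ systems whose SOFA component is explained by a chronic disease.

    A code contributes an organ iff its label reads as chronic-without-acute
    (case-insensitive word test) and its code matches the organ's ICD-10
    prefix set (cardiovascular I, coagulation D65-D69, renal N0-N3, liver
    K7, nervous G, respiration J). Malformed code strings are skipped with
    a warning.
    """
    mask: set[str] = set()
    for entry in codes:
        code = (entry.code or "").strip().upper()
        if not _CODE_RE.match(code):
            logger.warning("skipping malformed ICD-10 code %r", entry.code)
            continue
        if not _label_is_chronic(entry.label or ""):
            continue
        for organ, prefixes in ORGAN_CODE_PREFIXES.items():
            if code.startswith(prefixes):
                mask.add(organ)
    return frozenset(mask)


def adjudicate(record: PatientRecord,
               bands: Optional[BandConfig] = None) -> SepsisLabel:
    """Sepsis-3 label for one complete suspected-infection presentation."""
    return adjudicate_with_sofa(record, bands)[0]


def adjudicate_with_sofa(record: PatientRecord,
                         bands: Optional[BandConfig] = None
                         ) -> tuple[SepsisLabel, SofaBreakdown, OrganMask]:
    """As :func:`adjudicate`, also returning the SOFA breakdown and mask."""
    bands = bands or default_bands()
    if not record_is_complete(record, bands):
        raise ValidationError(
            f"record {record.id}: incomplete vitals; run filter_complete first")
    if not record.suspected_infection:
        raise ValidationError(
            f"record {record.id}: adjudication applies to suspected-infection patients")
    mask = chronic_mask(record.icd10_codes)
    sofa = compute_sofa(impute_labs(record.labs), record.vitals, mask, bands)
    label = SepsisLabel.SEPSIS if sofa.total >= SEPSIS_SOFA_MIN else SepsisLabel.NO_SEPSIS
    return label, sofa, mask
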