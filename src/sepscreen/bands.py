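"""Loading and validation of the score band tables.

The NEWS chart, SOFA thresholds, SpO2/FiO2 equivalence and GCS->AVPU map
ship as a versioned YAML file. Loading verifies a SHA-256 checksum so a
silently edited chart cannot produce plausible-looking but wrong scores;
``allow_custom=True`` (the ``--allow-custom-bands`` CLI flag) bypasses the
checksum for deliberately customised tables. Every numeric NEWS parameter's
bands are checked to partition its declared range with no gap or overlap by
an exhaustive sweep at the parameter's resolution.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .types import Avpu, ValidationError

#: SHA-256 of the bundled data/bands.yaml; recomputed when the chart is revised.
BUNDLED_BANDS_SHA256 = "db56b6df234b41f6abf5b44568de33132fa46a4403b3191eb77b47c5211ebe57"

_NUMERIC_NEWS_PARAMS = ("respiratory_rate", "spo2", "temperature", "systolic_bp", "heart_rate")


@dataclass(frozen=True)
class BandConfig:
    """Parsed and validated band tables."""

    version: int
    news: dict
    qsofa: dict
    sofa: dict
    sf_equivalence: dict
    gcs_to_avpu: dict
    checksum: str
    custom: bool = False

    def news_points(self, param: str, value) -> int:
        """Look up NEWS points for a numeric parameter value."""
        spec = self.news[param]
        resolution = spec.get("resolution", 1)
        v = round(round(value / resolution) * resolution, 10)
        for band in spec["bands"]:
            if band["lo"] <= v <= band["hi"]:
                return band["points"]
        lo, hi = spec["range"]
        raise ValidationError(f"{param}={value} outside admissible range [{lo}, {hi}]")


def _steps(lo, hi, resolution):
    n = round((hi - lo) / resolution)
    return [round(lo + i * resolution, 10) for i in range(n + 1)]


def _validate_partition(param: str, spec: dict) -> None:
    lo, hi = spec["range"]
    resolution = spec.get("resolution", 1)
    bands = spec["bands"]
    for v in _steps(lo, hi, resolution):
        hits = [b for b in bands if b["lo"] <= v <= b["hi"]]
        if len(hits) != 1:
            kind = "gap" if not hits else "overlap"
            raise ValidationError(f"NEWS band table for {param}: {kind} at value {v}")
    for b in bands:
        if b["points"] not in (0, 1, 2, 3):
            raise ValidationError(f"NEWS band table for {param}: invalid points {b['points']}")


def _validate(raw: dict) -> None:
    for param in _NUMERIC_NEWS_PARAMS:
        _validate_partition(param, raw["news"][param])
    o2 = raw["news"]["supplemental_o2"]
    if {o2["true"], o2["false"]} != {2, 0}:
        raise ValidationError("supplemental O2 must score 2 when present, 0 otherwise")
    avpu = raw["news"]["avpu"]
    if avpu["A"] != 0 or any(avpu[k] not in (0, 3) for k in ("V", "P", "U")):
        raise ValidationError("AVPU points must be 0 for A and 3 for non-alert levels")
    for key in ("respiration_pf", "coagulation_platelets", "cns_gcs"):
        cuts = raw["sofa"][key]["below"]
        if list(cuts) != sorted(cuts, reverse=True) or len(cuts) != 4:
            raise ValidationError(f"SOFA '{key}' cuts must be 4 descending thresholds")
    for key in ("liver_bilirubin", "renal_creatinine"):
        cuts = raw["sofa"][key]["above"]
        if list(cuts) != sorted(cuts) or len(cuts) != 3:
            raise ValidationError(f"SOFA '{key}' cuts must be 3 ascending thresholds")
    sf = raw["sf_equivalence"]["below"]
    if list(sf) != sorted(sf, reverse=True) or len(sf) != 4:
        raise ValidationError("S/F equivalence cuts must be 4 descending thresholds")
    gcs_map = raw["gcs_to_avpu"]
    lows = [gcs_map[k] for k in ("A", "V", "P", "U")]
    if lows[0] != 15 or lows[-1] != 3 or list(lows) != sorted(lows, reverse=True):
        raise ValidationError("GCS->AVPU map must be monotone with A at 15 and U reaching 3")


def _bundled_bytes() -> bytes:
    return resources.files("sepscreen.data").joinpath("bands.yaml").read_bytes()


def load_bands(path: Optional[str | Path] = None, allow_custom: bool = False) -> BandConfig:
    """Load band tables from ``path`` (default: the bundled chart).

    Raises :class:`ValidationError` if the checksum does not match the bundled
    chart and ``allow_custom`` is false, or if the tables are malformed.
    """
    data = Path(path).read_bytes() if path is not None else _bundled_bytes()
    checksum = hashlib.sha256(data).hexdigest()
    custom = checksum != BUNDLED_BANDS_SHA256
    if custom and not allow_custom:
        raise ValidationError(
            "band table checksum mismatch: pass allow_custom=True "
            "(--allow-custom-bands) to use a customised chart"
        )
    raw = yaml.safe_load(data)
    _validate(raw)
    gcs_map = {Avpu[k]: v for k, v in raw["gcs_to_avpu"].items()}
    return BandConfig(
        version=raw["version"],
        news=raw["news"],
        qsofa=raw["qsofa"],
        sofa=raw["sofa"],
        sf_equivalence=raw["sf_equivalence"],
        gcs_to_avpu=gcs_map,
        checksum=checksum,
        custom=custom,
    )


_DEFAULT: Optional[BandConfig] = None


def default_bands() -> BandConfig:
    """The bundled, checksum-verified band tables (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_bands()
    return _DEFAULT
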