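"""Score calculators: NEWS, qSOFA, SOFA, GCS->AVPU, SpO2/FiO2 fallback."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sepscreen as ss
from sepscreen.types import Avpu, Provenance

from .conftest import random_labs, random_vitals
from .oracles import news_chart, sofa_component_chart


def vitals(**overrides) -> ss.VitalSet:
    base = dict(respiratory_rate=16, spo2=98, supplemental_o2=False,
                temperature=37.0, systolic_bp=120, heart_rate=70, gcs=15)
    base.update(overrides)
    return ss.VitalSet(**base)


NORMAL_LABS = ss.LabPanel(pao2=95.0, fio2=0.21, platelets=250, bilirubin=10.0,
                          map=90, vasopressor=False, creatinine=80)


class TestNews:
    def test_boundary_patient_scores_four(self):
        """SBP 100 (band 91-100 -> 2) + RR 22 (band 21-24 -> 2), rest zero-band."""
        score = ss.compute_news(vitals(systolic_bp=100, respiratory_rate=22, spo2=96))
        assert score.total == 4
        assert score.components["systolic_bp"] == 2
        assert score.components["respiratory_rate"] == 2

    @pytest.mark.parametrize("overrides,total", [
        ({}, 0),
        ({"heart_rate": 115}, 2),            # HR band 111-130
        ({"spo2": 91}, 3),                   # SpO2 <= 91
        ({"supplemental_o2": True, "fio2": 0.28}, 2),
        ({"temperature": 38.1}, 1),          # band edge: 38.0 -> 0, 38.1 -> 1
        ({"temperature": 38.0}, 0),
        ({"avpu": Avpu.V, "gcs": None}, 3),
        ({"gcs": 12}, 3),                    # non-alert via GCS conversion
    ])
    def test_single_component_examples(self, overrides, total):
        assert ss.compute_news(vitals(**overrides)).total == total

    def test_missing_component_names_field(self):
        with pytest.raises(ss.IncompleteVitalsError, match="temperature"):
            ss.compute_news(vitals(temperature=None))

    def test_out_of_range_rejected(self):
        with pytest.raises(ss.ValidationError):
            vitals(spo2=140)

    def test_oracle_equivalence_sampled_grid(self):
        """Production band table vs an independently hand-encoded chart."""
        rng = np.random.default_rng(42)
        for _ in range(3000):
            v = random_vitals(rng)
            expected = news_chart(v.respiratory_rate, v.spo2, v.supplemental_o2,
                                  v.temperature, v.systolic_bp, v.heart_rate,
                                  alert=v.gcs == 15)
            assert ss.compute_news(v).total == expected, v

    def test_band_edge_fixtures_match_oracle(self, worked_examples):
        for name, record in worked_examples.items():
            if not name.startswith("edge_"):
                continue
            v = record.vitals
            avpu = v.avpu if v.avpu is not None else (Avpu.A if v.gcs == 15 else Avpu.V)
            alert = avpu is Avpu.A
            expected = news_chart(v.respiratory_rate, v.spo2, v.supplemental_o2,
                                  v.temperature, v.systolic_bp, v.heart_rate, alert)
            assert ss.compute_news(v).total == expected, name

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_component_sum(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        v = random_vitals(rng)
        score = ss.compute_news(v)
        assert 0 <= score.total <= 20
        assert score.total == sum(score.components.values())
        assert all(c in (0, 1, 2, 3) for k, c in score.components.items()
                   if k != "supplemental_o2")
        assert score.components["supplemental_o2"] in (0, 2)

    @given(st.integers(50, 219), st.integers(50, 100), st.integers(3, 15))
    @settings(max_examples=150, deadline=None)
    def test_worsening_monotonicity(self, sbp, spo2, gcs):
        """Lower SBP or SpO2, or GCS further from 15, never lowers NEWS/qSOFA.

        Holds below the hypertensive SBP band (>= 220 scores 3 in its own
        right), where the chart is deliberately non-monotone.
        """
        v_better = vitals(systolic_bp=sbp, spo2=spo2, gcs=gcs)
        for worse in (
            vitals(systolic_bp=max(40, sbp - 10), spo2=spo2, gcs=gcs),
            vitals(systolic_bp=sbp, spo2=max(50, spo2 - 5), gcs=gcs),
            vitals(systolic_bp=sbp, spo2=spo2, gcs=max(3, gcs - 2)),
        ):
            assert ss.compute_news(worse).total >= ss.compute_news(v_better).total
            assert ss.compute_qsofa(worse).total >= ss.compute_qsofa(v_better).total


class TestQsofa:
    @pytest.mark.parametrize("sbp,rr,gcs,total", [
        (100, 22, 15, 2),   # boundary patient
        (120, 16, 15, 0),
        (90, 24, 12, 3),
        (101, 21, 15, 0),   # just outside both thresholds
    ])
    def test_examples(self, sbp, rr, gcs, total):
        v = vitals(systolic_bp=sbp, respiratory_rate=rr, gcs=gcs)
        assert ss.compute_qsofa(v).total == total

    def test_altered_mentation_via_avpu(self):
        v = vitals(gcs=None, avpu=Avpu.P)
        assert ss.compute_qsofa(v).components["mentation"] == 1

    def test_missing_mentation_raises(self):
        with pytest.raises(ss.IncompleteVitalsError, match="mentation"):
            ss.compute_qsofa(vitals(gcs=None, avpu=None))


class TestGcsToAvpu:
    def test_endpoints(self):
        assert ss.gcs_to_avpu(15) is Avpu.A
        assert ss.gcs_to_avpu(3) is Avpu.U

    def test_exhaustive_monotone(self):
        levels = [ss.gcs_to_avpu(g) for g in range(3, 16)]
        assert set(levels) <= {Avpu.A, Avpu.V, Avpu.P, Avpu.U}
        # worsening GCS never improves the AVPU level
        assert all(a >= b for a, b in zip(levels, levels[1:]))
        assert ss.gcs_to_avpu(10) is Avpu.P

    def test_non_alert_gcs_scores_three_news_points(self):
        for g in range(3, 15):
            v = vitals(gcs=g)
            assert ss.compute_news(v).components["avpu"] == 3

    @pytest.mark.parametrize("bad", [2, 16, 0, -1, 7.5])
    def test_out_of_range(self, bad):
        with pytest.raises(ss.ValidationError):
            ss.gcs_to_avpu(bad)


class TestSofa:
    def test_all_normal_total_zero(self):
        sofa = ss.compute_sofa(NORMAL_LABS, vitals())
        assert sofa.total == 0
        assert all(p is Provenance.MEASURED for p in sofa.provenance.values())

    def test_chronic_renal_masking(self):
        labs = ss.LabPanel(pao2=95.0, fio2=0.21, platelets=250, bilirubin=10.0,
                           map=90, vasopressor=False, creatinine=500)
        sofa = ss.compute_sofa(labs, vitals(), mask=ss.organ_mask("renal"))
        assert sofa.total == 0
        assert sofa.provenance["renal"] is Provenance.MASKED

    def test_imputed_bilirubin_with_low_platelets(self):
        labs = ss.impute_labs(ss.LabPanel(pao2=95.0, fio2=0.21, platelets=90,
                                          map=90, vasopressor=False, creatinine=80))
        sofa = ss.compute_sofa(labs, vitals())
        assert (sofa.coagulation, sofa.liver, sofa.total) == (2, 0, 2)
        assert sofa.provenance["liver"] is Provenance.IMPUTED

    @pytest.mark.parametrize("organ,value,vaso", [
        ("coagulation", v, False) for v in (150, 149, 100, 99, 50, 49, 20, 19, 5)
    ] + [
        ("liver", v, False) for v in (19.9, 20, 32, 33, 101, 102, 204, 204.1, 500)
    ] + [
        ("renal", v, False) for v in (109, 110, 170, 171, 299, 300, 440, 441, 800)
    ] + [
        ("respiration", v, False) for v in (450, 400, 399, 300, 299, 200, 199, 100, 99)
    ] + [
        ("cns", v, False) for v in range(3, 16)
    ] + [
        ("cardiovascular", 80, False), ("cardiovascular", 69, False),
        ("cardiovascular", 50, True), ("cardiovascular", 90, True),
    ])
    def test_component_thresholds_match_published_table(self, organ, value, vaso):
        """Component-wise comparison against a second, hand-encoded SOFA table."""
        expected = sofa_component_chart(organ, value, vasopressor=vaso)
        labs = NORMAL_LABS
        v = vitals()
        if organ == "coagulation":
            labs = ss.LabPanel(**{**_lab_dict(), "platelets": value})
        elif organ == "liver":
            labs = ss.LabPanel(**{**_lab_dict(), "bilirubin": value})
        elif organ == "renal":
            labs = ss.LabPanel(**{**_lab_dict(), "creatinine": value})
        elif organ == "respiration":
            labs = ss.LabPanel(**{**_lab_dict(), "pao2": float(value), "fio2": 1.0})
        elif organ == "cns":
            v = vitals(gcs=value)
        elif organ == "cardiovascular":
            labs = ss.LabPanel(**{**_lab_dict(), "map": value, "vasopressor": vaso})
        sofa = ss.compute_sofa(labs, v)
        assert sofa.component(organ) == expected

    def test_pao2_unit_tag_kpa(self):
        mmhg = ss.LabPanel(**{**_lab_dict(), "pao2": 150.0, "fio2": 1.0})
        kpa = ss.LabPanel(**{**_lab_dict(), "pao2": 150.0 / 7.50062, "fio2": 1.0,
                             "pao2_unit": ss.PaO2Unit.KPA})
        v = vitals()
        assert ss.compute_sofa(mmhg, v).respiration == ss.compute_sofa(kpa, v).respiration == 3

    def test_unresolvable_component_names_organ(self):
        labs = ss.LabPanel(pao2=95.0, fio2=0.21, bilirubin=10.0, map=90,
                           vasopressor=False, creatinine=80)   # platelets absent
        with pytest.raises(ss.IncompleteLabsError, match="coagulation"):
            ss.compute_sofa(labs, vitals())

    @given(st.integers(0, 2**31 - 1), st.sets(st.sampled_from(ss.types.SOFA_ORGANS)))
    @settings(max_examples=120, deadline=None)
    def test_masking_never_raises_total(self, seed, mask):
        rng = np.random.default_rng(seed)
        labs = ss.impute_labs(random_labs(rng))
        v = random_vitals(rng)
        full = ss.compute_sofa(labs, v)
        masked = ss.compute_sofa(labs, v, mask=frozenset(mask))
        assert masked.total <= full.total
        for organ in mask:
            assert masked.component(organ) == 0


def _lab_dict() -> dict:
    return dict(pao2=95.0, fio2=0.21, platelets=250, bilirubin=10.0, map=90,
                vasopressor=False, creatinine=80)


class TestSpo2Fallback:
    def test_room_air_healthy_scores_zero(self):
        assert ss.sofa_respiratory_from_spo2(98, 0.21) == 0

    def test_sf_235_boundary_scores_two(self):
        assert ss.sofa_respiratory_from_spo2(94, 0.40) == 2   # S/F exactly 235

    def test_monotone_in_spo2(self):
        prev = -1
        for spo2 in range(97, 59, -1):
            comp = ss.sofa_respiratory_from_spo2(spo2, 0.40)
            assert comp >= prev
            prev = comp

    @pytest.mark.parametrize("spo2,fio2", [(0, 0.21), (95, 0.1), (95, 1.5), (101, 0.3)])
    def test_invalid_inputs(self, spo2, fio2):
        with pytest.raises(ss.ValidationError):
            ss.sofa_respiratory_from_spo2(spo2, fio2)

    def test_above_ceiling_on_supplemental_oxygen_capped(self):
        assert (ss.sofa_respiratory_from_spo2(99, 0.50)
                == ss.sofa_respiratory_from_spo2(97, 0.50))


def test_band_tables_refuse_unchecked_custom_chart(tmp_path, bands):
    custom = tmp_path / "bands.yaml"
    from importlib import resources
    text = resources.files("sepscreen.data").joinpath("bands.yaml").read_text()
    custom.write_text(text.replace("{lo: 21, hi: 24, points: 2}",
                                   "{lo: 21, hi: 24, points: 3}"))
    with pytest.raises(ss.ValidationError, match="checksum"):
        ss.load_bands(custom)
    modified = ss.load_bands(custom, allow_custom=True)
    assert modified.custom and modified.checksum != bands.checksum


def test_band_tables_reject_gap(tmp_path):
    from importlib import resources
    text = resources.files("sepscreen.data").joinpath("bands.yaml").read_text()
    broken = tmp_path / "bands.yaml"
    broken.write_text(text.replace("{lo: 21, hi: 24, points: 2}",
                                   "{lo: 22, hi: 24, points: 2}"))
    with pytest.raises(ss.ValidationError, match="gap"):
        ss.load_bands(broken, allow_custom=True)
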