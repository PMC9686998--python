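from __future__ import annotations

import numpy as np
import pytest

import sepscreen as ss
from sepscreen.pipeline import score_cohort
from sepscreen.synthetic import CohortConfig, generate_with_truth


@pytest.fixture(scope="session")
def bands():
    return ss.default_bands()


@pytest.fixture(scope="session")
def worked_examples():
    return {r.id: r for r in ss.generate_worked_examples()}


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition synthetic cohort with truth table (seed 1)."""
    records, truth = generate_with_truth(CohortConfig(seed=1))
    return records, truth


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """Adjudicated per-patient score table for the complete subset."""
    records, truth = default_cohort
    complete, excluded = ss.filter_complete(records)
    scored = score_cohort(complete)
    return scored, complete, excluded, truth


def random_vitals(rng: np.random.Generator) -> ss.VitalSet:
    """A random complete vital set across the full physiologic ranges."""
    return ss.VitalSet(
        respiratory_rate=int(rng.integers(0, 61)),
        spo2=int(rng.integers(50, 101)),
        supplemental_o2=bool(rng.integers(2)),
        temperature=round(float(rng.uniform(33.0, 42.0)), 1),
        systolic_bp=int(rng.integers(40, 251)),
        heart_rate=int(rng.integers(20, 201)),
        gcs=int(rng.integers(3, 16)),
    )


def random_labs(rng: np.random.Generator) -> ss.LabPanel:
    return ss.LabPanel(
        pao2=float(rng.uniform(40, 500)) if rng.random() < 0.5 else None,
        fio2=float(rng.uniform(0.21, 1.0)),
        platelets=float(rng.uniform(5, 400)),
        bilirubin=float(rng.uniform(1, 300)) if rng.random() < 0.5 else None,
        map=float(rng.uniform(40, 120)),
        vasopressor=bool(rng.random() < 0.2),
        creatinine=float(rng.uniform(30, 600)),
    )
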