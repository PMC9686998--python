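"""End-to-end screening analysis: score, adjudicate, evaluate, report.

``score_cohort`` turns complete patient records into a per-patient table of
NEWS, qSOFA, SOFA and the Sepsis-3 label; ``evaluate_cohort`` builds the
diagnostic report (three endpoints x two positivity rules x five metrics
with exact CIs, plus ROC/AUC per score per endpoint); ``reproduce_table``
re-derives a published accuracy table from its printed sensitivity/
specificity and group sizes. ``run_pipeline`` wires the stages together
behind the CLI with a run manifest for auditability.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .adjudication import adjudicate_with_sofa, filter_complete
from .bands import BandConfig, default_bands
from .diagnostics import (
    MetricEstimate,
    confusion,
    metrics,
    reconstruct_confusion,
    roc_with_ci,
)
from .scores import compute_panel
from .types import PatientRecord, SOFA_ORGANS, SepsisLabel

NEWS_THRESHOLD = 5      # NEWS >= 5 positivity rule
QSOFA_THRESHOLD = 2     # qSOFA >= 2 positivity rule

ENDPOINTS = ("sepsis", "icu", "mortality")
RULES = {"news": f"NEWS>={NEWS_THRESHOLD}", "qsofa": f"qSOFA>={QSOFA_THRESHOLD}"}


def published_summary() -> dict:
    """The shipped published summary inputs (group sizes, sens/spec)."""
    text = resources.files("sepscreen.data").joinpath(
        "published_screening_summary.json").read_text()
    return json.loads(text)


def score_cohort(records: Sequence[PatientRecord],
                 bands: Optional[BandConfig] = None) -> pd.DataFrame:
    """Score and adjudicate complete records into a per-patient table."""
    bands = bands or default_bands()
    rows = []
    for r in records:
        panel = compute_panel(r.vitals, bands)
        label, sofa, mask = adjudicate_with_sofa(r, bands)
        row = {
            "id": r.id,
            "news": panel.news.total,
            "qsofa": panel.qsofa.total,
            "sofa_total": sofa.total,
            "sepsis_label": label.value,
            "sepsis": label is SepsisLabel.SEPSIS,
            "icu": r.icu_admission,
            "mortality": r.death_28d,
        }
        for organ in SOFA_ORGANS:
            row[f"mask_{organ}"] = organ in mask
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_cohort(scored: pd.DataFrame, seed: int = 0,
                    auc_method: str = "delong") -> dict:
    """Diagnostic report over endpoints x rules, as a nested dict.

    For each endpoint (sepsis, ICU admission, 28-day mortality) and each
    positivity rule (NEWS >= 5, qSOFA >= 2): the 2x2 table, the five metrics
    with Clopper-Pearson 95% CIs, and the full-score ROC with AUC CI.
    """
    report: dict = {"n": int(len(scored)), "rules": dict(RULES),
                    "auc_ci_method": auc_method, "endpoints": {}}
    preds = {
        "news": scored["news"] >= NEWS_THRESHOLD,
        "qsofa": scored["qsofa"] >= QSOFA_THRESHOLD,
    }
    for endpoint in ENDPOINTS:
        y = scored[endpoint].to_numpy(dtype=bool)
        section: dict = {"n_pos": int(y.sum()), "n_neg": int((~y).sum())}
        for score_name in ("news", "qsofa"):
            cm = confusion(y, preds[score_name].to_numpy(), endpoint=endpoint,
                           rule=RULES[score_name])
            ms = metrics(cm)
            curve = roc_with_ci(scored[score_name].to_numpy(dtype=float), y,
                                endpoint=endpoint, score_name=score_name,
                                method=auc_method, seed=seed)
            section[score_name] = {
                "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
                "metrics": {name: _metric_dict(m) for name, m in ms.items()},
                "auc": curve.auc,
                "auc_ci": [curve.auc_ci_low, curve.auc_ci_high],
                "roc": {
                    "thresholds": [float(t) for t in curve.thresholds],
                    "tpr": curve.tpr.tolist(),
                    "fpr": curve.fpr.tolist(),
                },
            }
        report["endpoints"][endpoint] = section
    return report


def _metric_dict(m: MetricEstimate) -> dict:
    return {
        "point": m.point, "ci_low": m.ci_low, "ci_high": m.ci_high,
        "percent": m.percent, "ci_percent": list(m.ci_percent) if m.ci_percent else None,
        "defined": m.defined, "method": m.method,
    }


def report_to_table(report: dict) -> pd.DataFrame:
    """Flatten a diagnostic report into an accuracy-table-shaped frame."""
    rows = []
    for endpoint, section in report["endpoints"].items():
        for score_name in ("news", "qsofa"):
            entry = section[score_name]
            for metric_name, m in entry["metrics"].items():
                rows.append({
                    "endpoint": endpoint,
                    "rule": report["rules"][score_name],
                    "metric": metric_name,
                    "point": m["point"],
                    "ci_low": m["ci_low"],
                    "ci_high": m["ci_high"],
                    "percent": m["percent"],
                })
    return pd.DataFrame(rows)


def reproduce_table(summary: Optional[dict] = None) -> pd.DataFrame:
    """Re-derive a published screening accuracy table from printed summaries.

    For every endpoint and rule, rebuild the 2x2 table from the printed
    sensitivity/specificity and group sizes, then recompute all five metrics
    with exact CIs. Percentages are round-half-up, matching the published
    presentation.
    """
    summary = summary or published_summary()
    rows = []
    for endpoint, spec in summary["endpoints"].items():
        for score_name in ("news", "qsofa"):
            printed = spec[score_name]
            cm = reconstruct_confusion(printed["sensitivity"], printed["specificity"],
                                       spec["n_pos"], spec["n_neg"],
                                       endpoint=endpoint, rule=RULES[score_name])
            for name, m in metrics(cm).items():
                rows.append({
                    "endpoint": endpoint, "rule": RULES[score_name], "metric": name,
                    "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                    "point": m.point, "percent": m.percent,
                    "ci_low_percent": m.ci_percent[0], "ci_high_percent": m.ci_percent[1],
                })
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    seed: int
    package_version: str
    bands_checksum: str
    counts: dict            # stage -> record count
    outputs: dict           # name -> path
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def run_pipeline(out_dir: str | Path, seed: int = 0,
                 cohort: Optional[Sequence[PatientRecord]] = None,
                 config=None, bands: Optional[BandConfig] = None,
                 n_trees: int = 200, n_reps: int = 20,
                 importance_enabled: bool = True) -> RunManifest:
    """Generate (or take) a cohort, adjudicate, evaluate, and write reports."""
    from .cohort_io import write_cohort_csv
    from .importance import conditional_importance, features_from_records, fit_forest
    from .synthetic import CohortConfig, generate

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    bands = bands or default_bands()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        cfg = config or CohortConfig(seed=seed)
        cohort = generate(cfg)
    complete, excluded = filter_complete(cohort, bands)
    scored = score_cohort(complete, bands)
    report = evaluate_cohort(scored, seed=seed)

    outputs = {}
    cohort_path = out / "cohort.csv"
    write_cohort_csv(cohort, cohort_path, seed=seed, config_checksum=bands.checksum)
    outputs["cohort"] = str(cohort_path)

    scored_path = out / "adjudicated.csv"
    scored.to_csv(scored_path, index=False)
    outputs["adjudicated"] = str(scored_path)

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    outputs["report"] = str(report_path)

    table_path = out / "report_table.csv"
    report_to_table(report).to_csv(table_path, index=False)
    outputs["report_table"] = str(table_path)

    for endpoint in ENDPOINTS:
        for score_name in ("news", "qsofa"):
            roc_frame = pd.DataFrame(report["endpoints"][endpoint][score_name]["roc"])
            p = out / f"roc_{endpoint}_{score_name}.csv"
            roc_frame.to_csv(p, index=False)
            outputs[f"roc_{endpoint}_{score_name}"] = str(p)

    counts = {"input": len(list(cohort)), "complete": len(complete),
              "excluded": len(excluded)}

    if importance_enabled:
        X = features_from_records(complete)
        y = scored["sepsis"].to_numpy()
        model = fit_forest(X, y, n_trees=n_trees, seed=seed)
        imp = conditional_importance(model, n_reps=n_reps)
        imp_path = out / "importance.json"
        imp_path.write_text(json.dumps(imp.as_dict(), indent=2))
        outputs["importance"] = str(imp_path)
        pd.DataFrame(imp.as_dict()["variables"]).to_csv(out / "importance.csv", index=False)
        outputs["importance_csv"] = str(out / "importance.csv")

    manifest = RunManifest(
        seed=seed,
        package_version=__version__,
        bands_checksum=bands.checksum,
        counts=counts,
        outputs=outputs,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
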