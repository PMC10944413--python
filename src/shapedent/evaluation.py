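"""Scoring of per-tooth detection calls against ground-truth annotations.

Confusion conventions follow the forensic-odontology reading where a
present tooth is the positive class:

* TP — tooth present, called present
* TN — tooth absent, called missing
* FP — tooth absent, called present
* FN — tooth present, called missing

Exceptional findings (root remnant, implant, gap closure, first dentition)
are scored by their annotated binary truth like any other case and are
additionally tallied per category.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ShapedentError
from .tooth_detection import MANDIBULAR_FDI, DetectionResult

__all__ = [
    "CaseTruth",
    "ToothConfusion",
    "AccuracyReport",
    "confusion",
    "accuracy_report",
    "pearson_correlation",
    "group_comparison",
    "read_ground_truth",
    "write_ground_truth",
]

CATEGORIES = ("present", "absent", "root", "implant", "gap_closure", "first_dentition")


@dataclass
class CaseTruth:
    """Ground truth for one case: per-FDI binary truth (1 = present) and
    annotation category."""

    case_id: str
    binary: dict[int, int]
    category: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fdi, b in self.binary.items():
            if fdi not in MANDIBULAR_FDI:
                raise ValueError(f"{fdi} is not a mandibular FDI code")
            if b not in (0, 1):
                raise ValueError(f"binary truth for {fdi} must be 0 or 1, got {b}")
        for fdi, cat in self.category.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")


@dataclass
class ToothConfusion:
    """TP/TN/FP/FN counts per tooth, overall and per annotation category."""

    counts: dict[int, dict[str, int]]
    by_category: dict[str, dict[int, dict[str, int]]] = field(default_factory=dict)

    def total(self, fdi: int) -> int:
        c = self.counts[fdi]
        return c["tp"] + c["tn"] + c["fp"] + c["fn"]


@dataclass
class AccuracyReport:
    """Per-tooth accuracy (TP+TN)/(TP+TN+FP+FN) and its unweighted mean over
    the evaluable teeth."""

    per_tooth: dict[int, float]
    mean: float
    not_evaluable: list[int] = field(default_factory=list)
    group: str | None = None


def _empty_counts() -> dict[int, dict[str, int]]:
    return {fdi: {"tp": 0, "tn": 0, "fp": 0, "fn": 0} for fdi in MANDIBULAR_FDI}


def confusion(calls: list[DetectionResult], truth: list[CaseTruth]) -> ToothConfusion:
    """Tally the confusion counts of aligned call/truth case lists."""
    if len(calls) != len(truth):
        raise ValueError(
            f"{len(calls)} detection results vs {len(truth)} ground-truth cases"
        )
    counts = _empty_counts()
    by_category: dict[str, dict[int, dict[str, int]]] = {}
    for result, gt in zip(calls, truth):
        for tooth_call in result.calls:
            fdi = tooth_call.fdi
            if fdi not in gt.binary or tooth_call.call == "undetermined":
                continue
            present_truth = gt.binary[fdi] == 1
            called_present = tooth_call.call == "present"
            key = (
                "tp" if present_truth and called_present
                else "fn" if present_truth
                else "fp" if called_present
                else "tn"
            )
            counts[fdi][key] += 1
            cat = gt.category.get(fdi, "present" if present_truth else "absent")
            by_category.setdefault(cat, _empty_counts())[fdi][key] += 1
    return ToothConfusion(counts, by_category)


def accuracy_report(conf: ToothConfusion, group: str | None = None) -> AccuracyReport:
    per_tooth: dict[int, float] = {}
    not_evaluable: list[int] = []
    for fdi in MANDIBULAR_FDI:
        n = conf.total(fdi)
        if n == 0:
            not_evaluable.append(fdi)
            continue
        c = conf.counts[fdi]
        per_tooth[fdi] = (c["tp"] + c["tn"]) / n
    if not per_tooth:
        raise ShapedentError("no tooth has any evaluable case")
    if not_evaluable:
        warnings.warn(f"teeth without evaluable cases excluded from mean: {not_evaluable}")
    mean = float(np.mean(list(per_tooth.values())))
    return AccuracyReport(per_tooth, mean, not_evaluable, group)


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ShapedentError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def group_comparison(report_a: AccuracyReport, report_b: AccuracyReport):
    """Per-tooth absolute accuracy differences between two groups, their mean,
    and the Pearson correlation of the two accuracy vectors.

    The correlation is NaN (with a warning) when either vector has zero
    variance, e.g. for identical all-correct reports.
    """
    teeth = sorted(report_a.per_tooth)
    if teeth != sorted(report_b.per_tooth):
        raise ValueError("reports cover different tooth sets")
    a = np.array([report_a.per_tooth[f] for f in teeth])
    b = np.array([report_b.per_tooth[f] for f in teeth])
    diffs = {f: float(d) for f, d in zip(teeth, np.abs(a - b))}
    mean_abs = float(np.abs(a - b).mean())
    try:
        r = pearson_correlation(a, b)
    except ShapedentError:
        warnings.warn("zero variance in an accuracy vector; correlation undefined")
        r = float("nan")
    return diffs, mean_abs, r


# ---------------------------------------------------------------------------
# ground-truth tables
# ---------------------------------------------------------------------------

def read_ground_truth(path: str | Path) -> list[CaseTruth]:
    """Read a case_id,fdi_code,category,binary_truth CSV into CaseTruth records,
    preserving first-appearance case order."""
    df = pd.read_csv(path, dtype={"case_id": str})
    required = {"case_id", "fdi_code", "category", "binary_truth"}
    if not required.issubset(df.columns):
        raise ShapedentError(
            f"{path}: ground truth needs columns {sorted(required)}"
        )
    cases: list[CaseTruth] = []
    for case_id, grp in df.groupby("case_id", sort=False):
        binary = dict(zip(grp["fdi_code"].astype(int), grp["binary_truth"].astype(int)))
        category = dict(zip(grp["fdi_code"].astype(int), grp["category"]))
        cases.append(CaseTruth(str(case_id), binary, category))
    return cases


def write_ground_truth(cases: list[CaseTruth], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "fdi_code", "category", "binary_truth"])
        for case in cases:
            for fdi in sorted(case.binary):
                writer.writerow(
                    [
                        case.case_id,
                        fdi,
                        case.category.get(fdi, "present" if case.binary[fdi] else "absent"),
                        case.binary[fdi],
                    ]
                )


def report_to_json(report: AccuracyReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "group": report.group,
                "mean_accuracy": report.mean,
                "per_tooth": {str(k): v for k, v in report.per_tooth.items()},
                "not_evaluable": report.not_evaluable,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
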