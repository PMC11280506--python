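"""Confusion tallies and evaluation metrics for cut-point classification.

The primary stage evaluates the sedentary/active dichotomy; the secondary
stage the full sedentary/light/MV assignment. Per-class true-positive
rate (sensitivity), true-negative rate (specificity), and predicted
activity proportion (PAP: share of all epochs assigned to a class, true
and false positives alike) are combined into two overall ratings: MTPR,
the minimum TP rate over sedentary and the stage's top active class, and
PMR, 100 minus the total absolute deviation between gold and predicted
proportions. Rates are kept at full precision; rounding is for display
only.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    ACTIVE,
    LABELS2,
    LABELS3,
    MV,
    SED,
    ConfusionCounts,
    EpochRecord,
    EvaluationReport,
    ThresholdSet,
    to_primary,
)
from .features import classify_epochs


def confusion(
    gold: Sequence[str], predicted: Sequence[str], stage: str
) -> ConfusionCounts:
    """Cross-tabulate gold against predicted labels for one stage.

    In the primary stage LIGHT and MV collapse to ACTIVE on both sides.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label lists differ in length")
    if len(gold) == 0:
        raise ValueError("no labels to tabulate")
    classes = LABELS2 if stage == "primary" else LABELS3
    if stage == "primary":
        gold = [to_primary(g) for g in gold]
        predicted = [to_primary(p) for p in predicted]
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    for g, p in zip(gold, predicted):
        if g not in index or p not in index:
            raise ValueError(f"label not valid for stage {stage}: {g!r}/{p!r}")
        counts[index[g], index[p]] += 1
    return ConfusionCounts(stage, counts)


def tp_rate(counts: ConfusionCounts, cls: str) -> float:
    """Sensitivity for a class: 100 x correctly-predicted / gold total."""
    row = counts.row_total(cls)
    if row == 0:
        raise ValueError(f"no gold epochs of class {cls}")
    return 100.0 * counts.cell(cls, cls) / row


def tn_rate(counts: ConfusionCounts, cls: str) -> float:
    """Specificity for a class: among gold epochs NOT of the class, the
    share predicted as any label other than the class."""
    i = counts.classes.index(cls)
    mask = np.ones(len(counts.classes), dtype=bool)
    mask[i] = False
    complement_total = int(counts.counts[mask].sum())
    if complement_total == 0:
        raise ValueError(f"no gold epochs outside class {cls}")
    correct = int(counts.counts[np.ix_(mask, mask)].sum())
    return 100.0 * correct / complement_total


def pap(counts: ConfusionCounts, cls: str) -> float:
    """Predicted activity proportion: 100 x predicted column total / all."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * counts.col_total(cls) / counts.total


def pap_gold(counts: ConfusionCounts, cls: str) -> float:
    """Gold-standard activity proportion: 100 x gold row total / all."""
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    return 100.0 * counts.row_total(cls) / counts.total


def mtpr(report: EvaluationReport) -> float:
    """Minimum true-positive rate over the stage-relevant classes.

    Primary: min(TP_SED, TP_ACTIVE). Secondary: min(TP_SED, TP_MV) - the
    light class is deliberately excluded because the MV classification is
    the one health guidelines hinge on.
    """
    if report.stage == "primary":
        return min(report.tp_rate[SED], report.tp_rate[ACTIVE])
    return min(report.tp_rate[SED], report.tp_rate[MV])


def pmr(report: EvaluationReport) -> float:
    """PAP match rate: 100 minus the summed absolute deviation between
    gold and predicted activity proportions over the stage's classes."""
    classes = LABELS2 if report.stage == "primary" else LABELS3
    deviation = sum(abs(report.pap_gold[c] - report.pap[c]) for c in classes)
    return 100.0 - deviation


def build_report(counts: ConfusionCounts) -> EvaluationReport:
    """All per-class rates plus the MTPR and PMR overall ratings."""
    classes = counts.classes
    report = EvaluationReport(
        stage=counts.stage,
        tp_rate={c: tp_rate(counts, c) for c in classes},
        tn_rate={c: tn_rate(counts, c) for c in classes},
        pap={c: pap(counts, c) for c in classes},
        pap_gold={c: pap_gold(counts, c) for c in classes},
    )
    report.mtpr = mtpr(report)
    report.pmr = pmr(report)
    return report


def evaluate_epochs(
    epochs: Sequence[EpochRecord],
    thresholds: ThresholdSet,
    stage: str,
) -> tuple[ConfusionCounts, EvaluationReport]:
    """Classify epochs with a threshold set and evaluate against gold.

    Predictions are recomputed from the thresholds (the intended use is a
    held-out validation set, independent of the calibration epochs).
    """
    predicted = classify_epochs(list(epochs), thresholds)
    gold = [r.gold_label for r in epochs]
    counts = confusion(gold, predicted, stage)
    return counts, build_report(counts)


def format_report(report: EvaluationReport) -> str:
    """Human-readable metric table (rates rounded to 1 decimal)."""
    classes = LABELS2 if report.stage == "primary" else LABELS3
    lines = [f"stage: {report.stage}"]
    header = f"{'metric':<28}" + "".join(f"{c:>10}" for c in classes)
    lines.append(header)
    rows = [
        ("true positive rate (%)", report.tp_rate),
        ("true negative rate (%)", report.tn_rate),
        ("predicted proportion (%)", report.pap),
        ("gold proportion (%)", report.pap_gold),
    ]
    for name, values in rows:
        lines.append(f"{name:<28}" + "".join(f"{values[c]:>10.1f}" for c in classes))
    lines.append(f"{'MTPR (%)':<28}{report.mtpr:>10.1f}")
    lines.append(f"{'PMR (%)':<28}{report.pmr:>10.1f}")
    return "\n".join(lines)
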