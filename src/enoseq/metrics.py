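"""Regression and classification metrics, label mapping, report aggregation.

The network has a single regression head estimating normalized TVC; the
4-level quality classification is derived from it by de-normalizing the
output back to log CFU/g and applying the threshold mapping

    label = 1 (excellent)  if TVC < 3
            2 (good)       if 3 <= TVC < 4
            3 (acceptable) if 4 <= TVC < 5
            4 (spoiled)    if TVC >= 5

Reports aggregate per-cut MSE, accuracy and macro F1 across the model
stages (float-trained, post-quantization, retrained, deployed
fixed-point) the way the study tabulates them: 12 per-cut values plus
their arithmetic mean per stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import f1_score

__all__ = [
    "LABELS",
    "STAGES",
    "EvalReport",
    "mse",
    "tvc_to_label",
    "accuracy",
    "macro_f1",
    "aggregate_report",
]

LABELS = (1, 2, 3, 4)
STAGES = ("original_training", "fixed_point_selection", "retrain", "fixed_point_final")


def mse(y, y_pred) -> float:
    """Mean squared error, (1/N) Σ (y_i − y'_i)²."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError(f"length mismatch or empty input: {y.shape} vs {y_pred.shape}")
    return float(np.mean((y - y_pred) ** 2))


def tvc_to_label(tvc: float) -> int:
    """Quality label 1–4 from TVC on the original log-count scale."""
    tvc = float(tvc)
    if not np.isfinite(tvc):
        raise ValueError("TVC must be finite")
    if tvc < 3.0:
        return 1
    if tvc < 4.0:
        return 2
    if tvc < 5.0:
        return 3
    return 4


def accuracy(y, y_pred) -> float:
    """Fraction of exact label matches."""
    y = np.asarray(y)
    y_pred = np.asarray(y_pred)
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("length mismatch or empty input")
    return float(np.mean(y == y_pred))


def macro_f1(y, y_pred, labels: Sequence[int] = LABELS) -> float:
    """Unweighted mean over the fixed label set of per-label F1.

    Per-label F1 is the harmonic mean of precision and recall; a label
    absent from both sequences (or with zero-denominator precision or
    recall) contributes 0, with the label count fixed at ``len(labels)``.
    """
    y = np.asarray(y)
    y_pred = np.asarray(y_pred)
    if y.shape != y_pred.shape or y.size == 0:
        raise ValueError("length mismatch or empty input")
    return float(f1_score(y, y_pred, labels=list(labels), average="macro", zero_division=0))


@dataclass(frozen=True)
class EvalReport:
    """Per-cut and mean metrics for one model stage.

    Accuracy and macro F1 are in percent; MSE on the normalized-TVC
    scale.
    """

    stage: str
    cut_names: tuple[str, ...]
    mse_per_cut: np.ndarray
    accuracy_per_cut: np.ndarray  # percent
    macro_f1_per_cut: np.ndarray  # percent

    def __post_init__(self) -> None:
        n = len(self.cut_names)
        for arr in (self.mse_per_cut, self.accuracy_per_cut, self.macro_f1_per_cut):
            if len(arr) != n:
                raise ValueError("per-cut metric length mismatch")
        if np.any(self.mse_per_cut < 0):
            raise ValueError("negative MSE")
        for arr in (self.accuracy_per_cut, self.macro_f1_per_cut):
            if np.any(arr < 0) or np.any(arr > 100):
                raise ValueError("percent metric outside [0, 100]")

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.mse_per_cut))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy_per_cut))

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean(self.macro_f1_per_cut))


def aggregate_report(
    stage_metrics: Mapping[str, Mapping[str, Sequence[float]]],
    cut_names: Sequence[str],
    n_cuts: int = 12,
) -> tuple[dict[str, EvalReport], dict[str, float]]:
    """Build per-stage reports and cross-stage deltas.

    ``stage_metrics`` maps stage name -> {"mse": [...], "accuracy": [...],
    "macro_f1": [...]} with one value per cut (accuracy/F1 in percent).
    Deltas (first stage minus last stage, rounded to two decimals) are
    returned for mean accuracy and mean macro F1 — the study's headline
    "cost of deployment" numbers.
    """
    reports: dict[str, EvalReport] = {}
    for stage, m in stage_metrics.items():
        arrays = {k: np.asarray(v, dtype=np.float64) for k, v in m.items()}
        for k, v in arrays.items():
            if len(v) != n_cuts:
                raise ValueError(f"stage {stage}: expected {n_cuts} per-cut {k} values, got {len(v)}")
        reports[stage] = EvalReport(
            stage,
            tuple(cut_names),
            arrays["mse"],
            arrays["accuracy"],
            arrays["macro_f1"],
        )
    stages = list(reports)
    first, last = reports[stages[0]], reports[stages[-1]]
    deltas = {
        "accuracy": round(first.mean_accuracy - last.mean_accuracy, 2),
        "macro_f1": round(first.mean_macro_f1 - last.mean_macro_f1, 2),
    }
    return reports, deltas
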