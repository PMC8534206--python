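"""End-to-end workflow: preprocess → train → sweep → retrain → evaluate.

Stages, one independent model per cut, one global fixed-point format:

1. ``original_training`` — float models as trained (leaky rectifier).
2. ``fixed_point_selection`` — those models snapped to the selected
   (W, I) grid and run through the bit-accurate emulator.
3. ``retrain`` — models after 10 epochs of quantization-constrained
   retraining, evaluated in float.
4. ``fixed_point_final`` — the retrained (on-grid) models in the
   emulator: what the deployed hardware computes.

Per-cut metrics are computed on the held-out 20% test split: MSE on
the normalized TVC, and accuracy / macro F1 of the quality labels
obtained by de-normalizing the regression output and thresholding it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dtype_select import SweepResult, candidate_grid, run_sweep, save_sweep_csv
from .fxp import FixedPointFormat
from .metrics import EvalReport, STAGES, accuracy, aggregate_report, macro_f1, mse, tvc_to_label
from .mlp import MLPParams, forward_fixed, forward_float, init_params, quantize_params
from .preprocess import Normalizer, TVC_CHANNEL, preprocess_dataset
from .synthdata import CutSeries, SyntheticConfig, generate_dataset, read_dataset
from .training import DataSplit, SplitSpec, TrainConfig, retrain_quantized, split_cut, train_float

__all__ = ["PipelineConfig", "PipelineResult", "evaluate_stages", "run_pipeline"]

log = logging.getLogger("enoseq")

INITIAL_EPOCHS = 50
RETRAIN_EPOCHS = 10


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one full run. Exactly one data source: a directory
    of per-cut CSVs, or the synthetic generator (``synthetic=True``)."""

    synthetic: bool = True
    data_dir: str | Path | None = None
    seed: int = 0
    epochs: int = INITIAL_EPOCHS
    retrain_epochs: int = RETRAIN_EPOCHS
    learning_rate: float = 3e-4
    qat_mode: str = "ste"
    split: SplitSpec = field(default_factory=SplitSpec)
    candidates: tuple[FixedPointFormat, ...] | None = None
    sweep_on: str = "full"  # "full" curves (as plotted/scored) or "test" split
    synth: SyntheticConfig | None = None
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.synthetic == (self.data_dir is not None):
            raise ValueError("select exactly one data source: synthetic or data_dir")
        if self.sweep_on not in ("full", "test"):
            raise ValueError(f"unknown sweep_on {self.sweep_on!r}")


@dataclass
class PipelineResult:
    cuts: list[CutSeries]  # preprocessed
    normalizer: Normalizer
    splits: dict[str, DataSplit]
    float_models: dict[str, MLPParams]
    retrained_models: dict[str, MLPParams]
    sweep: SweepResult
    selected_format: FixedPointFormat
    reports: dict[str, EvalReport]
    deltas: dict[str, float]

    def regression_frame(self) -> pd.DataFrame:
        """MSE per stage and cut, scaled by 10^3 (reporting convention)."""
        rows = []
        for stage, rep in self.reports.items():
            row = {"stage": stage}
            row.update({c: m * 1e3 for c, m in zip(rep.cut_names, rep.mse_per_cut)})
            row["mean"] = rep.mean_mse * 1e3
            rows.append(row)
        return pd.DataFrame(rows)

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for stage, rep in self.reports.items():
            for metric, vals, mean in (
                ("accuracy", rep.accuracy_per_cut, rep.mean_accuracy),
                ("macro_f1", rep.macro_f1_per_cut, rep.mean_macro_f1),
            ):
                row = {"stage": stage, "metric": metric}
                row.update(dict(zip(rep.cut_names, vals)))
                row["mean"] = mean
                rows.append(row)
        return pd.DataFrame(rows)


def _cut_seed(base: int, cut_index: int, salt: int) -> int:
    return int((base * 10007 + salt * 131 + cut_index) % (2**31 - 1))


def _stage_metrics(
    pred_norm: np.ndarray,
    y_norm: np.ndarray,
    labels_true: np.ndarray,
    norm: Normalizer,
) -> tuple[float, float, float]:
    pred_tvc = norm.inverse_transform(pred_norm, TVC_CHANNEL)
    pred_labels = np.array([tvc_to_label(v) for v in pred_tvc])
    return (
        mse(y_norm, pred_norm),
        100.0 * accuracy(labels_true, pred_labels),
        100.0 * macro_f1(labels_true, pred_labels),
    )


def evaluate_stages(
    cuts: Sequence[CutSeries],
    splits: dict[str, DataSplit],
    float_models: dict[str, MLPParams],
    retrained: dict[str, MLPParams],
    fmt: FixedPointFormat,
    norm: Normalizer,
) -> tuple[dict[str, EvalReport], dict[str, float]]:
    """Per-cut test-split metrics for the four model stages."""
    stage_metrics = {s: {"mse": [], "accuracy": [], "macro_f1": []} for s in STAGES}
    for cut in cuts:
        _, _, (x_te, y_te, lab_te) = splits[cut.cut_name].subsets(cut)
        fp = float_models[cut.cut_name]
        rp = retrained[cut.cut_name]
        preds = {
            "original_training": forward_float(fp, x_te),
            "fixed_point_selection": forward_fixed(
                quantize_params(fp.with_mode("deploy"), fmt), x_te, fmt),
            "retrain": forward_float(rp, x_te),
            "fixed_point_final": forward_fixed(rp.with_mode("deploy"), x_te, fmt),
        }
        for stage, pred in preds.items():
            m, a, f1 = _stage_metrics(np.asarray(pred), y_te, lab_te, norm)
            stage_metrics[stage]["mse"].append(m)
            stage_metrics[stage]["accuracy"].append(a)
            stage_metrics[stage]["macro_f1"].append(f1)
    cut_names = [c.cut_name for c in cuts]
    return aggregate_report(stage_metrics, cut_names, n_cuts=len(cuts))


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; optionally write reports to ``cfg.out_dir``."""
    if cfg.synthetic:
        synth = cfg.synth if cfg.synth is not None else SyntheticConfig(seed=cfg.seed)
        raw = generate_dataset(synth)
        for cut in raw:
            cut.validate_labels()
        log.info("generated %d synthetic cuts (seed=%d)", len(raw), synth.seed)
    else:
        raw = read_dataset(cfg.data_dir)
        log.info("loaded %d cuts from %s", len(raw), cfg.data_dir)

    cuts, norm = preprocess_dataset(raw)
    log.info("preprocess: smoothed 11 sensor channels, global min-max normalization")

    splits: dict[str, DataSplit] = {}
    float_models: dict[str, MLPParams] = {}
    for i, cut in enumerate(cuts):
        spec = SplitSpec(cfg.split.train, cfg.split.validation, cfg.split.test,
                         seed=_cut_seed(cfg.seed, i, 1))
        splits[cut.cut_name] = split_cut(cut, spec)
        (x_tr, y_tr, _), (x_va, y_va, _), _ = splits[cut.cut_name].subsets(cut)
        params = init_params(seed=_cut_seed(cfg.seed, i, 2))
        tcfg = TrainConfig(cfg.epochs, cfg.learning_rate, seed=_cut_seed(cfg.seed, i, 3),
                           qat_mode=cfg.qat_mode)
        trained, log_df = train_float(params, (x_tr, y_tr), (x_va, y_va), tcfg)
        float_models[cut.cut_name] = trained
        log.info("train[%s]: %d epochs, final train MSE %.3e, val MSE %.3e (seed=%d)",
                 cut.cut_name, cfg.epochs, log_df.train_mse.iloc[-1],
                 log_df.val_mse.iloc[-1], tcfg.seed)

    if cfg.sweep_on == "test":
        sweep_cuts = []
        for cut in cuts:
            idx = splits[cut.cut_name].test_idx
            sweep_cuts.append(CutSeries(cut.cut_name, cut.time[idx], cut.sensors[idx],
                                        cut.tvc[idx], cut.label[idx]))
    else:
        sweep_cuts = cuts
    sweep = run_sweep(float_models, sweep_cuts, cfg.candidates)
    fmt = sweep.selected
    log.info("sweep: %d candidates, selected format %s (FoM %.3e)",
             len(sweep.candidates), fmt, sweep.fom_values[fmt])

    retrained: dict[str, MLPParams] = {}
    for i, cut in enumerate(cuts):
        (x_tr, y_tr, _), (x_va, y_va, _), _ = splits[cut.cut_name].subsets(cut)
        tcfg = TrainConfig(cfg.retrain_epochs, cfg.learning_rate,
                           seed=_cut_seed(cfg.seed, i, 4), qat_mode=cfg.qat_mode)
        rparams, _ = retrain_quantized(float_models[cut.cut_name], fmt,
                                       (x_tr, y_tr), (x_va, y_va), tcfg)
        retrained[cut.cut_name] = rparams
        log.info("retrain[%s]: %d epochs on %s grid", cut.cut_name, cfg.retrain_epochs, fmt)

    reports, deltas = evaluate_stages(cuts, splits, float_models, retrained, fmt, norm)
    log.info("evaluate: mean accuracy %s; deployment deltas %s",
             {s: round(r.mean_accuracy, 2) for s, r in reports.items()}, deltas)

    result = PipelineResult(cuts, norm, splits, float_models, retrained, sweep, fmt,
                            reports, deltas)
    if cfg.out_dir is not None:
        _write_reports(result, Path(cfg.out_dir))
    return result


def _write_reports(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.regression_frame().to_csv(out_dir / "regression_report.csv", index=False)
    result.classification_frame().to_csv(out_dir / "classification_report.csv", index=False)
    save_sweep_csv(result.sweep, out_dir / "sweep_report.csv")
    result.normalizer.save(out_dir / "normalizer.json")
    summary = {
        "selected_format": str(result.selected_format),
        "mean_accuracy": {s: r.mean_accuracy for s, r in result.reports.items()},
        "mean_macro_f1": {s: r.mean_macro_f1 for s, r in result.reports.items()},
        "mean_mse": {s: r.mean_mse for s, r in result.reports.items()},
        "deltas": result.deltas,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("reports written to %s", out_dir)
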