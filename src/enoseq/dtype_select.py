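"""Fixed-point candidate sweep and figure-of-merit datatype selection.

Wider words cost FPGA fabric: memory, DSP width, routing. The selection
procedure evaluates every candidate (W, I) format — W even in 8..16,
I in 2..4, fifteen formats — by quantizing each cut's float-trained
model, running the bit-accurate emulator over the cut's TVC curve, and
scoring the mean squared error against the true normalized TVC. A
figure of merit

    FoM = mean-MSE-over-cuts * W

balances accuracy against word length; the candidate minimizing it is
selected (ties break toward smaller W, then smaller I). The sweep uses
models quantized *without* retraining: selection happens first, the
10-epoch constrained retraining afterwards, on the winner only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fxp import FixedPointFormat
from .metrics import mse
from .mlp import MLPParams, forward_fixed, quantize_params
from .synthdata import CutSeries

__all__ = [
    "SweepResult",
    "candidate_grid",
    "evaluate_candidate",
    "fom",
    "select_format",
    "run_sweep",
]

SWEEP_W = (8, 10, 12, 14, 16)
SWEEP_I = (2, 3, 4)


def candidate_grid() -> list[FixedPointFormat]:
    """The 15 candidate formats: W in evens 8–16 crossed with I in 2–4."""
    return [FixedPointFormat(w, i) for w in SWEEP_W for i in SWEEP_I]


def fom(mean_mse: float, W: int) -> float:
    """Figure of merit: mean MSE across cuts times total bit count."""
    if mean_mse < 0 or W < 1:
        raise ValueError("need mean_mse >= 0 and W >= 1")
    return mean_mse * W


def evaluate_candidate(
    models: Mapping[str, MLPParams],
    cuts: Sequence[CutSeries],
    fmt: FixedPointFormat,
) -> tuple[dict[str, float], float]:
    """Per-cut emulated MSE for one candidate format, plus the mean.

    Each cut's model is quantized to ``fmt`` and run through the
    fixed-point emulator over the cut's series; the MSE is against the
    cut's normalized TVC.
    """
    per_cut: dict[str, float] = {}
    for cut in cuts:
        if cut.cut_name not in models:
            raise ValueError(f"no model for cut {cut.cut_name!r}")
        qp = quantize_params(models[cut.cut_name].with_mode("deploy"), fmt)
        pred = forward_fixed(qp, cut.sensors, fmt)
        per_cut[cut.cut_name] = mse(cut.tvc, pred)
    return per_cut, float(np.mean(list(per_cut.values())))


@dataclass(frozen=True)
class SweepResult:
    """Per-candidate per-cut MSE, mean MSE and FoM, plus the winner."""

    candidates: tuple[FixedPointFormat, ...]
    per_cut_mse: dict[FixedPointFormat, dict[str, float]]
    mean_mse: dict[FixedPointFormat, float]

    @property
    def fom_values(self) -> dict[FixedPointFormat, float]:
        return {f: fom(self.mean_mse[f], f.W) for f in self.candidates}

    @property
    def selected(self) -> FixedPointFormat:
        return select_format(self)

    def to_frame(self) -> pd.DataFrame:
        """Report table: one row per candidate, per-cut MSEs, mean, FoM."""
        foms = self.fom_values
        rows = []
        for f in self.candidates:
            row = {"format": str(f), "W": f.W, "I": f.I}
            row.update(self.per_cut_mse[f])
            row["mean_mse"] = self.mean_mse[f]
            row["fom"] = foms[f]
            rows.append(row)
        df = pd.DataFrame(rows)
        df["selected"] = df["format"] == str(self.selected)
        return df


def select_format(sweep: SweepResult) -> FixedPointFormat:
    """Argmin of the FoM; ties break toward smaller W, then smaller I."""
    if not sweep.candidates:
        raise ValueError("empty candidate list")
    foms = sweep.fom_values
    return min(sweep.candidates, key=lambda f: (foms[f], f.W, f.I))


def run_sweep(
    models: Mapping[str, MLPParams],
    cuts: Sequence[CutSeries],
    candidates: Sequence[FixedPointFormat] | None = None,
) -> SweepResult:
    """Evaluate every candidate over all cuts."""
    cands = tuple(candidates if candidates is not None else candidate_grid())
    per_cut: dict[FixedPointFormat, dict[str, float]] = {}
    means: dict[FixedPointFormat, float] = {}
    for f in cands:
        per_cut[f], means[f] = evaluate_candidate(models, cuts, f)
    return SweepResult(cands, per_cut, means)


def save_sweep_csv(sweep: SweepResult, path: str | Path) -> None:
    sweep.to_frame().to_csv(path, index=False)
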