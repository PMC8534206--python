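"""Sensor smoothing and dataset-wide min–max normalization.

MOS gas-sensor readings are noisy; a Savitzky–Golay filter (window 15,
polynomial order 5) smooths each of the 11 sensor channels. The TVC
target is *not* smoothed — its stepped assay resolution is part of the
ground truth. After filtering, every channel (sensors and TVC) is
min–max normalized with extrema pooled over all cuts:

    x' = (x - xmin) / (xmax - xmin)

so the network trains on [0, 1] inputs and a [0, 1] target, and
predicted labels are recovered later by inverting the TVC channel's
affine map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .synthdata import CutSeries, SENSOR_COLUMNS

__all__ = [
    "SAVGOL_WINDOW",
    "SAVGOL_POLYORDER",
    "Normalizer",
    "savgol_smooth",
    "fit_normalizer",
    "apply_normalizer",
    "preprocess_dataset",
]

SAVGOL_WINDOW = 15
SAVGOL_POLYORDER = 5
TVC_CHANNEL = "tvc"


def savgol_smooth(
    series: Sequence[float],
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_POLYORDER,
) -> np.ndarray:
    """Savitzky–Golay smoothing: local least-squares polynomial fits.

    Edges use the polynomial-extension mode (the window polynomial fit at
    each end is evaluated at the edge positions).
    """
    series = np.asarray(series, dtype=np.float64)
    if window % 2 != 1 or polyorder >= window:
        raise ValueError(f"need odd window > polyorder, got ({window}, {polyorder})")
    if len(series) < window:
        raise ValueError(f"series length {len(series)} shorter than window {window}")
    return savgol_filter(series, window_length=window, polyorder=polyorder, mode="interp")


@dataclass(frozen=True)
class Normalizer:
    """Per-channel pooled (xmin, xmax) for the 11 sensors and TVC."""

    xmin: dict[str, float]
    xmax: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.xmin) != set(self.xmax):
            raise ValueError("xmin/xmax channel sets differ")
        for ch in self.xmin:
            if not self.xmax[ch] > self.xmin[ch]:
                raise ValueError(f"degenerate range for channel {ch!r}: constant data")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.xmin)

    def transform(self, values, channel: str):
        if channel not in self.xmin:
            raise KeyError(f"unknown channel {channel!r}")
        lo, hi = self.xmin[channel], self.xmax[channel]
        return (np.asarray(values, dtype=np.float64) - lo) / (hi - lo)

    def inverse_transform(self, values, channel: str):
        if channel not in self.xmin:
            raise KeyError(f"unknown channel {channel!r}")
        lo, hi = self.xmin[channel], self.xmax[channel]
        return np.asarray(values, dtype=np.float64) * (hi - lo) + lo

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"xmin": self.xmin, "xmax": self.xmax}, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Normalizer":
        doc = json.loads(Path(path).read_text())
        return cls(dict(doc["xmin"]), dict(doc["xmax"]))


def _smooth_cut(cut: CutSeries, window: int, polyorder: int) -> CutSeries:
    sensors = np.column_stack(
        [savgol_smooth(cut.sensors[:, j], window, polyorder) for j in range(cut.sensors.shape[1])]
    )
    return replace(cut, sensors=sensors)


def fit_normalizer(cuts: Sequence[CutSeries]) -> Normalizer:
    """Pooled per-channel extrema over every cut in the dataset."""
    if len(cuts) == 0:
        raise ValueError("need at least one cut")
    xmin: dict[str, float] = {}
    xmax: dict[str, float] = {}
    for j, ch in enumerate(SENSOR_COLUMNS):
        pooled = np.concatenate([c.sensors[:, j] for c in cuts])
        xmin[ch], xmax[ch] = float(pooled.min()), float(pooled.max())
    pooled_tvc = np.concatenate([c.tvc for c in cuts])
    xmin[TVC_CHANNEL], xmax[TVC_CHANNEL] = float(pooled_tvc.min()), float(pooled_tvc.max())
    return Normalizer(xmin, xmax)


def apply_normalizer(series, channel: str, norm: Normalizer):
    """Elementwise (x − xmin)/(xmax − xmin) for one named channel."""
    return norm.transform(series, channel)


def preprocess_dataset(
    cuts: Sequence[CutSeries],
    window: int = SAVGOL_WINDOW,
    polyorder: int = SAVGOL_POLYORDER,
) -> tuple[list[CutSeries], Normalizer]:
    """Filter the sensor channels of every cut, then normalize globally.

    Sensor channels are smoothed and min–max scaled; TVC is scaled but
    not smoothed; labels pass through untouched. Returns the transformed
    cuts and the fitted normalizer (needed later to de-normalize network
    outputs back to log CFU/g).
    """
    smoothed = [_smooth_cut(c, window, polyorder) for c in cuts]
    norm = fit_normalizer(smoothed)
    out = []
    for cut in smoothed:
        sensors = np.column_stack(
            [norm.transform(cut.sensors[:, j], ch) for j, ch in enumerate(SENSOR_COLUMNS)]
        )
        tvc = norm.transform(cut.tvc, TVC_CHANNEL)
        out.append(replace(cut, sensors=sensors, tvc=tvc))
    return out, norm
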