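"""Synthetic beef-cut e-nose datasets and the per-cut CSV layout.

The real study monitors 12 beef cuts for 2220 minutes each: the total
viable count (TVC, log CFU/g) rises sigmoidally as the microbial
population grows, the plating/optical TVC assay only resolves coarse
steps (hence a staircase-looking curve), a 4-level quality label is cut
from the TVC at 3, 4 and 5 log units, and 11 metal-oxide gas sensors
respond — noisily and with channel-specific gain and baseline — to the
spoilage volatiles that track the microbial load.

The generator reproduces exactly that statistical structure:

* ``tvc(t)``: a logistic curve from ``tvc_floor`` to ``tvc_ceiling``
  with per-cut jittered growth rate and midpoint, floored to
  ``tvc_step`` to emulate the assay's stepped resolution;
* ``sensor_i(t) = b_i + a_i * tvc_norm(t) + N(0, sd_i)``, with gains
  ``a_i`` of alternating sign across channels so the array is
  heterogeneous but informative;
* labels derived from the *stepped* TVC through the threshold mapping.

Everything is deterministic under ``(seed, cut_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metrics import tvc_to_label

__all__ = [
    "CUT_NAMES",
    "SENSOR_COLUMNS",
    "CutSeries",
    "SyntheticConfig",
    "generate_cut",
    "generate_dataset",
    "read_cut_csv",
    "write_cut_csv",
]

# The 12 cuts monitored in the deposited beef dataset.
CUT_NAMES = (
    "inside_outside",
    "round",
    "top_sirloin",
    "tenderloin",
    "flap_meat",
    "striploin",
    "rib_eye",
    "skirt_meat",
    "brisket",
    "clod_chuck",
    "shin",
    "fat",
)

N_SENSORS = 11
SENSOR_COLUMNS = tuple(f"s{i:02d}" for i in range(1, N_SENSORS + 1))
CSV_COLUMNS = ("time_min",) + SENSOR_COLUMNS + ("tvc", "label")


@dataclass
class CutSeries:
    """One cut's time series: 11 sensor channels, TVC and quality label."""

    cut_name: str
    time: np.ndarray  # minutes, 0..T-1
    sensors: np.ndarray  # (T, 11)
    tvc: np.ndarray  # log CFU/g, stepped, non-decreasing
    label: np.ndarray  # 1..4, = tvc_to_label(tvc)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=np.float64)
        self.sensors = np.asarray(self.sensors, dtype=np.float64)
        self.tvc = np.asarray(self.tvc, dtype=np.float64)
        self.label = np.asarray(self.label, dtype=np.int64)
        t = len(self.time)
        if self.sensors.shape != (t, N_SENSORS) or len(self.tvc) != t or len(self.label) != t:
            raise ValueError("channel lengths inconsistent")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.sensors, columns=list(SENSOR_COLUMNS))
        df.insert(0, "time_min", self.time)
        df["tvc"] = self.tvc
        df["label"] = self.label
        return df

    def validate_labels(self) -> None:
        """Assert label consistency with the TVC threshold mapping."""
        expect = np.array([tvc_to_label(v) for v in self.tvc])
        if not np.array_equal(expect, self.label):
            raise ValueError(f"cut {self.cut_name}: labels inconsistent with TVC thresholds")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the 12-cut beef study."""

    n_cuts: int = 12
    n_minutes: int = 2220
    tvc_floor: float = 2.2  # log CFU/g at the start of spoilage
    tvc_ceiling: float = 8.5  # saturated late-spoilage plateau
    growth_rate: float = 0.005  # logistic rate, per minute
    midpoint_min: float = 1100.0  # logistic midpoint, jittered per cut
    midpoint_jitter: float = 150.0
    rate_jitter: float = 0.15  # relative jitter on growth_rate
    tvc_step: float = 0.25  # assay resolution (stepped TVC)
    gain_low: float = 1.0  # per-channel |gain| range
    gain_high: float = 4.0
    baseline_low: float = 0.5
    baseline_high: float = 5.0
    noise_sd: float = 0.1  # sensor noise sd, as a fraction of |gain|
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tvc_floor < 3.0 and self.tvc_ceiling > 5.0):
            raise ValueError("TVC span must cross the 3/4/5 label thresholds")
        if self.noise_sd < 0 or self.tvc_step <= 0 or self.growth_rate <= 0:
            raise ValueError("invalid synthetic configuration")
        if self.n_cuts < 1 or self.n_minutes < 1:
            raise ValueError("invalid synthetic configuration")


def _channel_params(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel gain, baseline and noise sd (shared across cuts)."""
    rng = np.random.default_rng([int(cfg.seed), 977])
    gains = rng.uniform(cfg.gain_low, cfg.gain_high, size=N_SENSORS)
    gains *= np.where(np.arange(N_SENSORS) % 2 == 0, 1.0, -1.0)  # MOS channels respond both ways
    baselines = rng.uniform(cfg.baseline_low, cfg.baseline_high, size=N_SENSORS)
    sds = cfg.noise_sd * np.abs(gains)
    return gains, baselines, sds


def generate_cut(cfg: SyntheticConfig, cut_index: int) -> CutSeries:
    """One synthetic cut, deterministic under ``(cfg.seed, cut_index)``."""
    if not (0 <= cut_index < cfg.n_cuts):
        raise ValueError(f"cut_index {cut_index} outside 0..{cfg.n_cuts - 1}")
    rng = np.random.default_rng([int(cfg.seed), int(cut_index)])
    t = np.arange(cfg.n_minutes, dtype=np.float64)

    k = cfg.growth_rate * (1.0 + rng.uniform(-cfg.rate_jitter, cfg.rate_jitter))
    t0 = cfg.midpoint_min + rng.uniform(-cfg.midpoint_jitter, cfg.midpoint_jitter)
    span = cfg.tvc_ceiling - cfg.tvc_floor
    smooth = cfg.tvc_floor + span / (1.0 + np.exp(-k * (t - t0)))
    tvc = np.floor(smooth / cfg.tvc_step) * cfg.tvc_step  # assay step resolution

    gains, baselines, sds = _channel_params(cfg)
    tvc_norm = (tvc - cfg.tvc_floor) / span
    clean = baselines[None, :] + gains[None, :] * tvc_norm[:, None]
    noise = rng.standard_normal((cfg.n_minutes, N_SENSORS)) * sds[None, :]
    sensors = clean + noise

    label = np.array([tvc_to_label(v) for v in tvc], dtype=np.int64)
    name = CUT_NAMES[cut_index] if cut_index < len(CUT_NAMES) else f"cut_{cut_index:02d}"
    return CutSeries(name, t, sensors, tvc, label)


def generate_dataset(cfg: SyntheticConfig) -> list[CutSeries]:
    """All ``cfg.n_cuts`` cuts; reproducible under ``cfg.seed``."""
    return [generate_cut(cfg, i) for i in range(cfg.n_cuts)]


def write_cut_csv(cut: CutSeries, path: str | Path) -> None:
    cut.to_frame().to_csv(path, index=False)


def read_cut_csv(path: str | Path, cut_name: str | None = None) -> CutSeries:
    """Read one cut's CSV; columns are mapped by name, order-insensitive."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - set(CSV_COLUMNS)
    if extra:
        raise ValueError(f"{path}: unexpected columns {sorted(extra)}")
    for col in CSV_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]) or df[col].isna().any():
            raise ValueError(f"{path}: non-numeric values in column {col}")
    name = cut_name if cut_name is not None else path.stem
    return CutSeries(
        name,
        df["time_min"].to_numpy(dtype=np.float64),
        df[list(SENSOR_COLUMNS)].to_numpy(dtype=np.float64),
        df["tvc"].to_numpy(dtype=np.float64),
        df["label"].to_numpy(dtype=np.int64),
    )


def write_dataset(cuts: Iterable[CutSeries], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cut in cuts:
        p = out_dir / f"{cut.cut_name}.csv"
        write_cut_csv(cut, p)
        paths.append(p)
    return paths


def read_dataset(data_dir: str | Path) -> list[CutSeries]:
    files = sorted(Path(data_dir).glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no cut CSVs found in {data_dir}")
    return [read_cut_csv(p) for p in files]
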