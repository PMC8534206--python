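"""Per-cut network training and quantization-constrained retraining.

Each beef cut gets its own model, trained on a random 60/20/20
train/validation/test split of its 2220 samples. Initial training runs
50 epochs of Adam (lr 3e-4, batch size 1) on the squared-error loss
with the leaky-rectifier network. After the fixed-point format is
chosen, a 10-epoch retraining with the same hyperparameters pulls the
parameters onto the chosen (W, I) grid: the forward pass uses
grid-quantized weights while full-precision shadow weights receive the
gradient updates (straight-through estimator), with a final
snap-to-grid. A plain projection variant (quantize after every Adam
step) is available via ``qat_mode="project"``.

The network is small enough (793 parameters) that training runs on a
flat parameter vector with per-layer views; one Adam step is a handful
of length-793 vector operations, which keeps batch-size-1 training fast
in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fxp import FixedPointFormat
from .mlp import MLPParams, count_params, forward_float, init_params, quantize_params
from .synthdata import CutSeries

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "DataSplit",
    "split_cut",
    "train_float",
    "retrain_quantized",
]

ADAM_BETA1 = 0.9
ADAM_BETA2 = 0.999
ADAM_EPS = 1e-8  # PyTorch Adam defaults


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation/test split fractions and seed."""

    train: float = 0.6
    validation: float = 0.2
    test: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must be positive and sum to 1, got {fracs}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (initial: 50 epochs; retrain: 10)."""

    epochs: int = 50
    learning_rate: float = 3e-4
    batch_size: int = 1
    seed: int = 0
    qat_mode: str = "ste"  # "ste" or "project", used by retrain_quantized

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if self.qat_mode not in ("ste", "project"):
            raise ValueError(f"unknown qat_mode {self.qat_mode!r}")


@dataclass(frozen=True)
class DataSplit:
    """Index sets of one cut's split, plus the design matrices."""

    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def subsets(self, cut: CutSeries):
        return tuple(
            (cut.sensors[idx], cut.tvc[idx], cut.label[idx])
            for idx in (self.train_idx, self.val_idx, self.test_idx)
        )


def split_cut(cut: CutSeries, spec: SplitSpec) -> DataSplit:
    """Random disjoint split; sizes floored, remainder goes to train.

    2220 samples under the default 60/20/20 fractions give exactly
    (1332, 444, 444).
    """
    n = len(cut)
    if n < 5:
        raise ValueError(f"cut {cut.cut_name} has only {n} samples")
    n_val = int(np.floor(spec.validation * n))
    n_test = int(np.floor(spec.test * n))
    perm = np.random.default_rng(spec.seed).permutation(n)
    val = np.sort(perm[:n_val])
    test = np.sort(perm[n_val : n_val + n_test])
    train = np.sort(perm[n_val + n_test :])
    return DataSplit(train, val, test)


class _FlatNet:
    """Mutable flat parameter vector with per-layer weight/bias views."""

    def __init__(self, params: MLPParams):
        self.arch = params.architecture
        self.slope = params.lrelu_slope
        self.theta = params.flat()
        self.w_views, self.b_views = self._views(self.theta)

    def _views(self, vec: np.ndarray):
        w_views, b_views, ofs = [], [], 0
        for n_in, n_out in zip(self.arch[:-1], self.arch[1:]):
            w_views.append(vec[ofs : ofs + n_out * n_in].reshape(n_out, n_in))
            ofs += n_out * n_in
            b_views.append(vec[ofs : ofs + n_out])
            ofs += n_out
        return w_views, b_views

    def to_params(self, mode: str = "train") -> MLPParams:
        return MLPParams.from_flat(self.arch, self.theta, mode, self.slope)


def _sgd_pass(
    net: _FlatNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    order: np.ndarray,
    lr: float,
    adam_state: dict,
    fmt: FixedPointFormat | None,
    qat_mode: str,
) -> None:
    """One epoch of batch-size-1 Adam on the squared-error loss.

    With ``fmt`` set and ``qat_mode="ste"``, the forward/backward uses
    grid-quantized parameters while updates land on the float shadow
    vector; with ``"project"`` the parameters themselves are snapped
    after every step.
    """
    slope = net.slope
    theta = net.theta
    n_layers = len(net.w_views)
    grad = adam_state["grad"]
    gw_views, gb_views = net._views(grad)
    m, v = adam_state["m"], adam_state["v"]

    if fmt is not None and qat_mode == "ste":
        scale = 2.0 ** (fmt.W - fmt.I)
        lo, hi = -(2.0 ** (fmt.W - 1)), 2.0 ** (fmt.W - 1) - 1.0
        qbuf = adam_state["qbuf"]
        qw_views, qb_views = net._views(qbuf)
    else:
        qw_views, qb_views = net.w_views, net.b_views

    acts = [None] * (n_layers + 1)
    pre = [None] * n_layers

    for i in order:
        if fmt is not None and qat_mode == "ste":
            np.multiply(theta, scale, out=qbuf)
            np.round(qbuf, out=qbuf)
            np.clip(qbuf, lo, hi, out=qbuf)
            qbuf /= scale

        a = x_train[i]
        acts[0] = a
        for k in range(n_layers):
            z = qw_views[k] @ a + qb_views[k]
            pre[k] = z
            a = np.where(z > 0, z, slope * z)
            acts[k + 1] = a

        # squared error on the scalar head
        delta = np.asarray([2.0 * (acts[-1][0] - y_train[i])])
        for k in range(n_layers - 1, -1, -1):
            delta = delta * np.where(pre[k] > 0, 1.0, slope)
            gw_views[k][...] = np.outer(delta, acts[k])
            gb_views[k][...] = delta
            if k > 0:
                delta = qw_views[k].T @ delta

        adam_state["t"] += 1
        t = adam_state["t"]
        m *= ADAM_BETA1
        m += (1.0 - ADAM_BETA1) * grad
        v *= ADAM_BETA2
        v += (1.0 - ADAM_BETA2) * grad * grad
        step = lr * np.sqrt(1.0 - ADAM_BETA2**t) / (1.0 - ADAM_BETA1**t)
        theta -= step * m / (np.sqrt(v) + ADAM_EPS)

        if fmt is not None and qat_mode == "project":
            theta[...] = np.clip(np.round(theta * (2.0 ** (fmt.W - fmt.I))),
                                 -(2.0 ** (fmt.W - 1)), 2.0 ** (fmt.W - 1) - 1.0) \
                / (2.0 ** (fmt.W - fmt.I))


def _fit(
    params: MLPParams,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    fmt: FixedPointFormat | None,
) -> tuple[MLPParams, pd.DataFrame]:
    x_tr, y_tr = (np.asarray(a, dtype=np.float64) for a in train_set)
    x_va, y_va = (np.asarray(a, dtype=np.float64) for a in val_set)
    net = _FlatNet(params)
    n_par = count_params(params.architecture)
    adam_state = {
        "m": np.zeros(n_par),
        "v": np.zeros(n_par),
        "grad": np.zeros(n_par),
        "qbuf": np.zeros(n_par),
        "t": 0,
    }
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_tr))
        _sgd_pass(net, x_tr, y_tr, order, cfg.learning_rate, adam_state, fmt, cfg.qat_mode)
        eval_params = net.to_params("train")
        if fmt is not None:
            eval_params = quantize_params(eval_params, fmt)
        tr_mse = float(np.mean((forward_float(eval_params, x_tr) - y_tr) ** 2))
        va_mse = float(np.mean((forward_float(eval_params, x_va) - y_va) ** 2))
        if not (np.isfinite(tr_mse) and np.isfinite(va_mse)):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        rows.append({"epoch": epoch, "train_mse": tr_mse, "val_mse": va_mse})
    out = net.to_params(params.activation_mode)
    if fmt is not None:
        out = quantize_params(out, fmt)  # final snap-to-grid
    return out, pd.DataFrame(rows)


def train_float(
    params: MLPParams,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[MLPParams, pd.DataFrame]:
    """Floating-point training; returns parameters after exactly
    ``cfg.epochs`` epochs plus the per-epoch train/validation MSE log.
    No early stopping; validation is monitoring only."""
    return _fit(params, train_set, val_set, cfg, fmt=None)


def retrain_quantized(
    params: MLPParams,
    fmt: FixedPointFormat,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
) -> tuple[MLPParams, pd.DataFrame]:
    """Quantization-constrained retraining onto the ``fmt`` grid.

    Every returned weight and bias is exactly representable in ``fmt``.
    """
    return _fit(params, fmt=fmt, train_set=train_set, val_set=val_set, cfg=cfg)
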