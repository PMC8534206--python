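"""The 11-32-12-1 fully connected network.

Two forward paths share one parameter set:

* ``forward_float`` — the training-time network. Each layer computes
  ``y = f(Wx + b)`` where ``f`` is a leaky rectifier (slope 0.01) in
  ``train`` mode or a plain rectifier in ``deploy`` mode. The leaky
  variant keeps gradients alive during optimisation; the deployed
  hardware replaces it with ReLU because that removes a multiply.
* ``forward_fixed`` — a bit-accurate emulation of the deployed
  fixed-point datapath: inputs quantized to the ``(W, I)`` grid,
  exact multiply-accumulate per layer (hardware accumulators are
  wide enough that intermediates never round), ReLU, then the layer
  output is quantized back to the grid before feeding the next layer.

Products of two ``(W, I)`` grid values and their short sums are exact in
64-bit floats for all supported ``W``, so the emulator returns exactly
the values an integer datapath would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .fxp import FixedPointFormat, is_representable, quantize

__all__ = [
    "MLPParams",
    "DEFAULT_ARCHITECTURE",
    "count_params",
    "lrelu",
    "relu",
    "init_params",
    "forward_float",
    "forward_fixed",
    "quantize_params",
    "save_params",
    "load_params",
]

DEFAULT_ARCHITECTURE = (11, 32, 12, 1)
DEFAULT_LRELU_SLOPE = 0.01


def count_params(architecture: Sequence[int]) -> int:
    """Total weight + bias count of a fully connected net: Σ (n_i·n_{i+1} + n_{i+1})."""
    arch = list(architecture)
    if len(arch) < 2:
        raise ValueError("architecture needs at least input and output layers")
    if any(int(n) < 1 for n in arch):
        raise ValueError("all layer widths must be >= 1")
    return sum(arch[i] * arch[i + 1] + arch[i + 1] for i in range(len(arch) - 1))


def lrelu(x, slope: float = DEFAULT_LRELU_SLOPE):
    """Leaky rectifier: ``x`` if ``x > 0`` else ``slope * x``."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, x, slope * x)
    return float(out) if out.ndim == 0 else out


def relu(x):
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x > 0, x, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MLPParams:
    """Weights and biases of the fully connected net.

    ``weights[k]`` has shape ``(out_k, in_k)``; ``biases[k]`` shape
    ``(out_k,)``. ``activation_mode`` selects the rectifier applied at
    every layer including the output: ``"train"`` (leaky) or
    ``"deploy"`` (plain).
    """

    architecture: tuple[int, ...]
    weights: tuple[np.ndarray, ...]
    biases: tuple[np.ndarray, ...]
    activation_mode: str = "train"
    lrelu_slope: float = DEFAULT_LRELU_SLOPE
    format_tag: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.activation_mode not in ("train", "deploy"):
            raise ValueError(f"unknown activation_mode {self.activation_mode!r}")
        arch = tuple(int(n) for n in self.architecture)
        if len(self.weights) != len(arch) - 1 or len(self.biases) != len(arch) - 1:
            raise ValueError("layer count inconsistent with architecture")
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (arch[k + 1], arch[k]) or b.shape != (arch[k + 1],):
                raise ValueError(
                    f"layer {k} shapes {w.shape}/{b.shape} inconsistent with {arch}"
                )

    @property
    def n_params(self) -> int:
        return count_params(self.architecture)

    def with_mode(self, mode: str) -> "MLPParams":
        return replace(self, activation_mode=mode)

    def map_arrays(self, fn: Callable[[np.ndarray], np.ndarray]) -> "MLPParams":
        """Apply ``fn`` to every weight matrix and bias vector."""
        return replace(
            self,
            weights=tuple(np.asarray(fn(w), dtype=np.float64) for w in self.weights),
            biases=tuple(np.asarray(fn(b), dtype=np.float64) for b in self.biases),
        )

    def flat(self) -> np.ndarray:
        """All parameters concatenated (layer order, W then b, row-major)."""
        return np.concatenate(
            [a.ravel() for pair in zip(self.weights, self.biases) for a in pair]
        )

    @classmethod
    def from_flat(
        cls,
        architecture: Sequence[int],
        flat: np.ndarray,
        activation_mode: str = "train",
        lrelu_slope: float = DEFAULT_LRELU_SLOPE,
        format_tag: str | None = None,
    ) -> "MLPParams":
        arch = tuple(int(n) for n in architecture)
        flat = np.asarray(flat, dtype=np.float64)
        if flat.size != count_params(arch):
            raise ValueError("flat vector length inconsistent with architecture")
        weights, biases, ofs = [], [], 0
        for k in range(len(arch) - 1):
            n_in, n_out = arch[k], arch[k + 1]
            weights.append(flat[ofs : ofs + n_out * n_in].reshape(n_out, n_in).copy())
            ofs += n_out * n_in
            biases.append(flat[ofs : ofs + n_out].copy())
            ofs += n_out
        return cls(arch, tuple(weights), tuple(biases), activation_mode, lrelu_slope, format_tag)


def init_params(
    architecture: Sequence[int] = DEFAULT_ARCHITECTURE,
    seed: int | np.random.Generator = 0,
    activation_mode: str = "train",
) -> MLPParams:
    """Fresh network with weights and biases uniform in ±sqrt(1/fan_in)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arch = tuple(int(n) for n in architecture)
    weights, biases = [], []
    for n_in, n_out in zip(arch[:-1], arch[1:]):
        bound = np.sqrt(1.0 / n_in)
        weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
        biases.append(rng.uniform(-bound, bound, size=n_out))
    return MLPParams(arch, tuple(weights), tuple(biases), activation_mode)


def _activation(params: MLPParams):
    if params.activation_mode == "train":
        slope = params.lrelu_slope
        return lambda z: np.where(z > 0, z, slope * z)
    return lambda z: np.where(z > 0, z, 0.0)


def forward_float(params: MLPParams, x) -> float | np.ndarray:
    """Floating-point forward pass.

    ``x`` is one input vector (length ``architecture[0]``) or a matrix of
    row vectors; returns a scalar or a vector of scalar outputs.
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    a = np.atleast_2d(x)
    if a.shape[1] != params.architecture[0]:
        raise ValueError(f"input width {a.shape[1]} != {params.architecture[0]}")
    act = _activation(params)
    for w, b in zip(params.weights, params.biases):
        a = act(a @ w.T + b)
    out = a[:, 0]
    return float(out[0]) if single else out


def forward_fixed(params: MLPParams, x, fmt: FixedPointFormat) -> float | np.ndarray:
    """Bit-accurate fixed-point forward pass (deployed-network emulator).

    Parameters must already lie on the ``fmt`` grid (see
    :func:`quantize_params`). Inputs are quantized to the grid; each
    layer's multiply-accumulate is exact, ReLU is applied, and the layer
    output is quantized (round-half-to-even, saturating) before the next
    layer. The result is always representable in ``fmt``.
    """
    for arr in (*params.weights, *params.biases):
        if not is_representable(arr, fmt):
            raise ValueError(f"parameters are not on the {fmt} grid; quantize_params first")
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    a = quantize(np.atleast_2d(x), fmt)
    if a.shape[1] != params.architecture[0]:
        raise ValueError(f"input width {a.shape[1]} != {params.architecture[0]}")
    for w, b in zip(params.weights, params.biases):
        z = a @ w.T + b  # exact MAC: hardware accumulator never rounds
        a = quantize(np.where(z > 0, z, 0.0), fmt)
    out = a[:, 0]
    return float(out[0]) if single else out


def quantize_params(params: MLPParams, fmt: FixedPointFormat) -> MLPParams:
    """Snap every weight and bias to the ``fmt`` grid; architecture unchanged."""
    out = params.map_arrays(lambda a: quantize(a, fmt))
    return replace(out, format_tag=str(fmt))


def save_params(params: MLPParams, path: str | Path) -> None:
    """Serialize to JSON: architecture, per-layer row-major weights, biases."""
    doc = {
        "architecture": list(params.architecture),
        "layers": [
            {"weights": w.tolist(), "bias": b.tolist()}
            for w, b in zip(params.weights, params.biases)
        ],
        "activation_mode": params.activation_mode,
        "lrelu_slope": params.lrelu_slope,
        "format": params.format_tag,
    }
    Path(path).write_text(json.dumps(doc))


def load_params(path: str | Path) -> MLPParams:
    doc = json.loads(Path(path).read_text())
    weights = tuple(np.asarray(l["weights"], dtype=np.float64) for l in doc["layers"])
    biases = tuple(np.asarray(l["bias"], dtype=np.float64) for l in doc["layers"])
    return MLPParams(
        tuple(doc["architecture"]),
        weights,
        biases,
        doc.get("activation_mode", "train"),
        doc.get("lrelu_slope", DEFAULT_LRELU_SLOPE),
        doc.get("format"),
    )
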