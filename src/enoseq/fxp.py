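"""Signed fixed-point formats, quantization and saturation.

A ``(W, I)`` format is a two's-complement signed binary number with ``W``
total bits of which ``I`` (including the sign bit) encode the integer part.
Its representable values form a grid of exactly ``2**W`` points spaced
``2**-(W-I)`` apart on ``[-2**(I-1), 2**(I-1) - 2**-(W-I)]``.

For ``W <= 32`` every grid value is an exact binary fraction representable
in a 64-bit float, so quantization and the downstream inference emulator
are bit-exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FixedPointFormat",
    "FormatError",
    "format_range",
    "quantize",
    "is_representable",
]

MAX_TOTAL_BITS = 32


class FormatError(ValueError):
    """Invalid (W, I) combination."""


@dataclass(frozen=True, order=True)
class FixedPointFormat:
    """A signed fixed-point type with ``W`` total and ``I`` integer bits.

    ``I`` counts the sign bit, so the format covers
    ``[-2**(I-1), 2**(I-1) - resolution]`` with ``resolution = 2**-(W-I)``.
    """

    W: int
    I: int

    def __post_init__(self) -> None:
        if not (isinstance(self.W, (int, np.integer)) and isinstance(self.I, (int, np.integer))):
            raise FormatError(f"W and I must be integers, got ({self.W!r}, {self.I!r})")
        if self.W < 2:
            raise FormatError(f"need W >= 2, got W={self.W}")
        if not (1 <= self.I <= self.W):
            raise FormatError(f"need 1 <= I <= W, got (W, I)=({self.W}, {self.I})")
        if self.W > MAX_TOTAL_BITS:
            raise FormatError(f"W={self.W} exceeds supported maximum {MAX_TOTAL_BITS}")

    @property
    def resolution(self) -> float:
        return 2.0 ** -(self.W - self.I)

    @property
    def min(self) -> float:
        return -(2.0 ** (self.I - 1))

    @property
    def max(self) -> float:
        return 2.0 ** (self.I - 1) - self.resolution

    def __str__(self) -> str:
        return f"({self.W},{self.I})"

    @classmethod
    def parse(cls, text: str) -> "FixedPointFormat":
        """Parse the ``"(W,I)"`` serialization, e.g. ``"(10,2)"``."""
        m = re.fullmatch(r"\(\s*(\d+)\s*,\s*(\d+)\s*\)", text.strip())
        if m is None:
            raise FormatError(f"cannot parse fixed-point format {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


def format_range(fmt: FixedPointFormat) -> tuple[float, float, float]:
    """Return ``(min, max, resolution)`` of the representable grid."""
    return (fmt.min, fmt.max, fmt.resolution)


def quantize(value, fmt: FixedPointFormat):
    """Round ``value`` to the nearest grid point of ``fmt``, saturating.

    Rounding is round-half-to-even; out-of-range values clamp to the
    nearest bound (saturation, not wrap-around). Accepts scalars or
    arrays; idempotent on its own output.
    """
    arr = np.asarray(value, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("quantize requires finite input")
    scale = 2.0 ** (fmt.W - fmt.I)
    lo = -(2.0 ** (fmt.W - 1))
    hi = 2.0 ** (fmt.W - 1) - 1.0
    # np.round is round-half-to-even, matching the integer oracle
    q = np.clip(np.round(arr * scale), lo, hi) / scale
    if np.isscalar(value) or np.ndim(value) == 0:
        return float(q)
    return q


def is_representable(value: float, fmt: FixedPointFormat) -> bool:
    """True iff ``value`` lies exactly on the grid of ``fmt``."""
    v = np.asarray(value, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("is_representable requires finite input")
    return bool(np.all(quantize(v, fmt) == v))
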