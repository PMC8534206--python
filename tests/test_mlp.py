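"""Network forward passes: float training path and fixed-point emulator."""

from fractions import Fraction

import numpy as np
import pytest

from enoseq.fxp import FixedPointFormat, is_representable, quantize
from enoseq.mlp import (
    MLPParams,
    count_params,
    forward_fixed,
    forward_float,
    init_params,
    load_params,
    lrelu,
    quantize_params,
    save_params,
)


def oracle_forward_fixed(params: MLPParams, x, fmt: FixedPointFormat) -> float:
    """All-integer reference datapath: values held as ints scaled by 2^(W-I)."""
    scale = 2 ** (fmt.W - fmt.I)
    lo, hi = -(2 ** (fmt.W - 1)), 2 ** (fmt.W - 1) - 1

    def to_int(v):
        q = round(Fraction(float(v)) * scale)
        return max(lo, min(hi, q))

    a = [to_int(v) for v in x]
    for w, b in zip(params.weights, params.biases):
        w_int = [[int(v * scale) for v in row] for row in w]  # params already on grid
        b_int = [int(v * scale) for v in b]
        out = []
        for i in range(len(b_int)):
            acc = b_int[i] * scale + sum(w_int[i][j] * a[j] for j in range(len(a)))
            acc = max(acc, 0)  # ReLU in accumulator units (scale^2)
            out.append(max(lo, min(hi, round(Fraction(acc, scale)))))
        a = out
    return float(Fraction(a[0], scale))


@pytest.mark.parametrize(
    "arch, expect",
    [([11, 32, 12, 1], 793), ([1, 1], 2), ([2, 3, 1], 13)],
)
def test_count_params(arch, expect):
    assert count_params(arch) == expect


def test_count_params_rejects_degenerate():
    with pytest.raises(ValueError):
        count_params([5])


@pytest.mark.parametrize("x, expect", [(2.0, 2.0), (-1.0, -0.01), (0.0, 0.0)])
def test_lrelu(x, expect):
    assert lrelu(x) == expect


class TestForwardFloat:
    def test_zero_weights_bias_passthrough(self):
        p = init_params(seed=0).map_arrays(np.zeros_like)
        beta = 0.7
        biases = list(p.biases)
        biases[-1] = np.array([beta])
        p = MLPParams(p.architecture, p.weights, tuple(biases))
        assert forward_float(p, np.ones(11)) == pytest.approx(beta)

    def test_single_layer_sum(self):
        p = MLPParams((2, 1), (np.array([[1.0, 1.0]]),), (np.zeros(1),), "deploy")
        assert forward_float(p, np.array([0.2, 0.3])) == pytest.approx(0.5)

    def test_train_deploy_agree_on_nonnegative_preactivations(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = init_params([3, 4, 1], seed=rng.integers(2**31))
            p = p.map_arrays(np.abs)  # non-negative weights and biases
            x = rng.uniform(0, 1, 3)  # -> all pre-activations >= 0
            assert forward_float(p, x) == pytest.approx(
                forward_float(p.with_mode("deploy"), x)
            )

    def test_shape_error(self):
        with pytest.raises(ValueError):
            forward_float(init_params(seed=0), np.ones(7))

    def test_batch_matches_single(self):
        p = init_params(seed=9)
        x = np.random.default_rng(0).uniform(0, 1, (5, 11))
        batch = forward_float(p, x)
        assert np.allclose(batch, [forward_float(p, row) for row in x])


class TestForwardFixed:
    fmt = FixedPointFormat(10, 2)

    def test_all_zero_params_output_zero(self):
        p = init_params(seed=0).map_arrays(np.zeros_like)
        assert forward_fixed(p, np.random.default_rng(0).uniform(0, 1, 11), self.fmt) == 0.0

    def test_identity_layer_passes_on_grid_input(self):
        p = MLPParams((1, 1), (np.array([[1.0]]),), (np.zeros(1),), "deploy")
        assert forward_fixed(p, np.array([0.5]), self.fmt) == 0.5

    def test_off_grid_params_rejected(self):
        p = init_params(seed=1)  # fresh params are generically off-grid
        with pytest.raises(ValueError):
            forward_fixed(p, np.ones(11), self.fmt)

    def test_output_always_representable_and_nonnegative(self):
        rng = np.random.default_rng(5)
        p = quantize_params(init_params(seed=2), self.fmt)
        for _ in range(100):
            y = forward_fixed(p, rng.uniform(-1, 2, 11), self.fmt)
            assert y >= 0.0
            assert is_representable(y, self.fmt)

    def test_matches_integer_mac_oracle_random_networks(self):
        """Bit-exactness against an all-integer datapath on tiny random nets."""
        rng = np.random.default_rng(7)
        fmts = [FixedPointFormat(w, i) for w in (8, 10, 12, 16) for i in (2, 4)]
        for trial in range(300):
            fmt = fmts[trial % len(fmts)]
            arch = [int(rng.integers(1, 5)) for _ in range(int(rng.integers(2, 5)))]
            p = quantize_params(init_params(arch, seed=int(rng.integers(2**31))), fmt)
            x = rng.uniform(-2, 2, arch[0])
            assert forward_fixed(p, x, fmt) == oracle_forward_fixed(p, x, fmt)

    def test_error_shrinks_with_word_length(self):
        """At fixed I, wider words track the float deploy output ever closer."""
        rng = np.random.default_rng(11)
        p = init_params(seed=4)
        xs = rng.uniform(0, 1, (50, 11))
        errs = []
        for w in (8, 10, 12, 14, 16):
            fmt = FixedPointFormat(w, 2)
            qp = quantize_params(p.with_mode("deploy"), fmt)
            err = np.mean(
                (forward_fixed(qp, xs, fmt) - forward_float(p.with_mode("deploy"), xs)) ** 2
            )
            errs.append(err)
        assert errs[-1] < errs[0]
        assert errs[-1] < 1e-6


def test_save_load_roundtrip(tmp_path):
    p = quantize_params(init_params(seed=6), FixedPointFormat(12, 3))
    save_params(p, tmp_path / "p.json")
    back = load_params(tmp_path / "p.json")
    assert back.architecture == p.architecture
    assert back.format_tag == "(12,3)"
    for a, b in zip(p.weights + p.biases, back.weights + back.biases):
        assert np.array_equal(a, b)
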