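# Methods

## Problem and model

An electronic nose — an array of 11 metal-oxide-semiconductor (MOS) gas
sensors — monitors a beef cut once per minute for 2220 minutes while it
spoils. The regression target is the Total Viable Count (TVC), the
log-scale microbial load, which also defines a 4-level quality label
(excellent / good / acceptable / spoiled) cut at 3, 4 and 5 log units.
One small fully connected network per cut,

    11 → 32 → 12 → 1   (793 parameters),   y = f(Wx + b) per layer,

maps the 11 normalized sensor readings at one time step to the
normalized TVC. During training `f` is a leaky rectifier
(`LReLU(x) = x` if `x > 0`, else `0.01·x`), which avoids dead units;
the deployed network substitutes the plain rectifier, which is cheaper
in hardware and changes nothing once inputs to the non-linearity are
rarely negative at convergence. The activation is applied at every
layer including the scalar output head; the normalized TVC is
non-negative, so the output-side rectifier is benign.

Classification is derived, not separately trained: the regression
output is mapped back to log CFU/g by inverting the TVC channel's
min–max normalization and thresholded at 3/4/5.

## Preprocessing

Sensor channels are smoothed with a Savitzky–Golay filter (window 15,
polynomial order 5; polynomial-extension edge handling, since nothing
constrains the edges otherwise). The TVC is *not* smoothed — its
staircase shape reflects the assay's resolution and is part of the
ground truth. After filtering, every channel (sensors and TVC) is
min–max normalized with extrema pooled over all 12 cuts, so a single
affine map per channel serves the whole dataset. Pooling happens before
the train/validation/test split; the only quantities that leak are
per-channel extrema, which is the intended protocol here.

## Training

Each cut's 2220 samples are split at random into 60 % train / 20 %
validation / 20 % test (1332/444/444; floor rounding, remainder to
train). Training is Adam (betas 0.9/0.999, eps 1e-8) with learning rate
3·10⁻⁴, batch size 1, 50 epochs, squared-error loss, no early stopping;
the validation curve is recorded but never used for selection. The
sample order is reshuffled every epoch under the run seed, and training
is bit-reproducible for a fixed seed. The optimiser, backward pass and
network run on a flat 793-element parameter vector with per-layer
views, which keeps batch-size-1 training in pure numpy at roughly
3 s per cut per 50 epochs on one CPU core.

## Fixed-point emulation

A signed (W, I) fixed-point format has W total bits, I of them
(including the sign) for the integer part: a two's-complement grid of
2^W values spaced 2^−(W−I) on [−2^(I−1), 2^(I−1) − 2^−(W−I)].
Quantization rounds half-to-even and saturates at the range bounds
(wrap-around would corrupt regression outputs silently). All grid
values for W ≤ 32 are exact binary fractions, so 64-bit floats emulate
the integer datapath bit-exactly; the test suite checks this against an
all-integer/rational oracle.

The inference emulator quantizes the input vector, computes each
layer's multiply-accumulate exactly (hardware accumulators are wider
than the operand format, so intermediates never round), applies ReLU,
and quantizes the layer output back to the grid before the next layer.
Its output is therefore always representable in the chosen format and
non-negative.

## Datatype selection and retraining

Candidates are the 15 formats with W ∈ {8, 10, 12, 14, 16} and
I ∈ {2, 3, 4}. For each candidate, every cut's float-trained model is
snapped to the grid (no retraining at this stage — selection comes
first) and the emulator is scored over the cut's whole TVC curve; the
figure of merit

    FoM = (mean MSE over cuts) · W

penalizes word length as a proxy for fabric cost, and the candidate
minimizing it wins, ties broken toward smaller W then smaller I.
A config switch restricts sweep scoring to the test split instead of
the whole curve.

The winner's models are then retrained for 10 epochs with the same
hyperparameters under a straight-through estimator: the forward and
backward passes use grid-quantized parameters (leaky-rectifier mode, as
in initial training) while Adam updates full-precision shadow
parameters, and the result is snapped to the grid, so every returned
weight and bias is exactly representable. A pure projection variant
(snap after every optimiser step) is available via
`TrainConfig(qat_mode="project")` for comparison; the straight-through
route is the default because projection at coarse grids can stall — the
per-step update (lr 3·10⁻⁴) is usually smaller than one grid step
(2⁻⁸ ≈ 3.9·10⁻³ for (10, 2)).

## Evaluation stages

Reports cover four stages per cut: the float model as trained
(`original_training`), its post-hoc quantization in the emulator
(`fixed_point_selection`), the retrained model evaluated in float
(`retrain`), and the retrained model in the emulator
(`fixed_point_final`) — the last is what the deployed hardware
computes. Metrics per cut and stage: MSE on the normalized TVC
(reported ×10³), plus accuracy and macro F1 (in percent) of the derived
labels on the test split. Macro F1 averages per-label F1 over the fixed
label set {1, 2, 3, 4}; a label absent from both truth and prediction,
or any zero-denominator precision/recall, contributes 0. The headline
deltas are first-stage minus last-stage mean accuracy and mean macro
F1, rounded to two decimals.

## Synthetic data

The generator reproduces the study's structure so that the whole
workflow is testable without the deposited dataset: 12 cuts × 2220
minutes × 11 channels. TVC follows a logistic growth curve from 2.2 to
8.5 log CFU/g (crossing all three label thresholds) with rate
0.005 min⁻¹ and midpoint 1100 min, both jittered per cut (±15 %,
±150 min), floored to 0.25-log steps to emulate assay resolution.
Sensors are affine in the normalized TVC with per-channel gains
|a| ~ U(1, 4) of alternating sign, baselines U(0.5, 5) and white
Gaussian noise with sd = 0.1·|a| — the simplest model that makes the
11-channel regression well-posed yet noisy enough for the smoothing
step to matter. Not emulated: per-gas MOS chemistry and
cross-sensitivities, sensor drift, temperature/humidity covariates, and
any nonlinear sensor saturation. Passing end-to-end tests therefore
demonstrates the correctness and stability of the *pipeline* —
training, selection, quantization, retraining, scoring — not field
performance on real meat.

## Numerical choices and degenerate inputs

* Rounding: half-to-even everywhere (quantizer and emulator); the
  hardware-side rounding mode is a genuine unknown, and truncation
  would shift low-order output bits.
* Weight init: uniform ±√(1/fan_in) per layer, seeded.
* Degenerate guards: formats need 2 ≤ W ≤ 32, 1 ≤ I ≤ W; constant
  channels fail normalization; series shorter than the filter window,
  cuts with < 5 samples, NaN losses and off-grid parameters passed to
  the emulator all raise.
* Per-cut seeds for split, init, shuffling and retraining are derived
  deterministically from the run seed, so a single integer reproduces a
  run byte-for-byte.

## Problem sizes used in the checked runs

The default test/acceptance runs use the full study geometry (12 cuts ×
2220 samples, 50 + 10 epochs); the multi-seed deployment-gap check uses
five seeds. CLI smoke tests use reduced epochs only to exercise the
plumbing.

## Known limitations

* Per-cut metric values of the original study are not reproducible
  bit-for-bit even against the deposited data: its seeds and split
  realizations are unpublished. Aggregate behaviour (deployment gap of
  order one accuracy point, MSE shrinking with W) is the reproducible
  content.
* One global format for all layers; no per-layer mixed precision.
* The emulator models rounding only at layer outputs; hardware with a
  narrow accumulator would differ.
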