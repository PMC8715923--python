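# Methods

This note records the model definitions, default constants, and the
numerical/design choices behind them. Everything here is implemented in
`src/spikecim/` and exercised by the test suite.

## 1. Spike encoding (`encoding.py`)

A normalized sample `I ∈ [0,1]^{C×L}` becomes a binary train over `T`
discrete steps: at each step every position fires iff a fresh uniform draw
`X < I`. Draws are i.i.d. across steps, so per-position spike counts are
Binomial(T, I) with mean `T·I` — the rate-coding ("Poisson encoder")
regime. Encoding is deterministic given `(sample, T, seed)`; one
`numpy.random.default_rng(seed)` per call. Strict `<` makes `I = 0` silent
and `I = 1` fire every step.

## 2. Adaptive LIF neuron (`neuron.py`)

Discrete-time leaky integrator with unit resistance:

    u[t+1] = k_τ · u[t] + I · R0,     spike when u ≥ V_th, hard reset to 0

- The spike is emitted in the same step the threshold is crossed (boundary
  inclusive), and reset is to exactly zero, not threshold subtraction.
- Pre-synaptic drive is clamped: `I = max(I0, 0)`. Together with the
  subtracted adaptive branch (below) this prevents runaway firing.
- Defaults: `k_τ = 0.8`, `R0 = 1`, `V_th = 0.5` (one constant per layer is
  supported), surrogate width `a = 1`.
- Surrogate derivative for training: rectangular pulse
  `h(u) = a` on `|u − V_th| ≤ a/2`, else 0 (boundary inclusive).

Under constant subthreshold drive the membrane follows the geometric
closed form `u[t] = I·R0·(1 − k_τ^t)/(1 − k_τ)`, which the tests check to
1e−10 over 1,000 steps.

## 3. Network topology (`network.py`)

For 1×251 inputs and 4 classes, in order (out, in, kernel):

    SConv1(4,1,3) → SConv2(16,4,3) → MaxPool2
    → SConv3(16,16,3) → SConv4(16,16,2) → SConv5(32,16,2) → MaxPool2
    → FC1(1888→128) → FC2(128→4)

Valid (no-padding) stride-1 convolution; pooling floor-divides the length
(a trailing odd sample is dropped). Length chain:
251 → 249 → 247 → 123 → 121 → 120 → 119 → 59; flatten 32·59 = 1888.

Every SConv/FC block has two independent weight sets; the drive is
`I0 = Σ (w − β·w_a)·o_prev` with `β = 0.25` by default. Pooling on binary
spikes is a logical OR over non-overlapping windows. All inter-block
traffic is strictly binary (validated at runtime, asserted in tests).
Readout: per-class output-spike counter over the `T` steps; argmax with
ties broken toward the lowest class index. Initialization: uniform
`±1/√fan_in`, independent draws for `w` and `w_a`, seeded.

## 4. Training (`training.py`)

Loss is the rate-MSE between one-hot labels and output firing rates:

    L = (1/2M) Σ_m ‖ y_m − (1/T) Σ_t o_{m,t} ‖²

Backpropagation runs through layers and through time (STBP). The spike
nonlinearity uses the rectangular surrogate `h(u)`; the temporal path
carries `k_τ` per step and is **zeroed after a spike** (the hard reset is
treated as a non-differentiable gate). The clamp contributes its exact
derivative (indicator of `I0 ≥ 0`).

**Gradient oracle.** Finite differences of a spiking loss are meaningless
(piecewise-constant). The tests therefore difference a *surrogate-relaxed*
model: the spike is replaced by the piecewise-linear ramp
`s(u) = clip(a·(u − V_th + a/2), 0, a²)` — whose derivative is exactly
`h(u)` — while the hard reset gate is kept. For that model the analytic
STBP backward is the exact gradient; the measured maximum relative error
vs central differences is ~6e−8 (threshold 1e−4) on toy FC and conv+pool
networks.

Defaults: Adam, `lr = 1e−3`, batch 25, 30 epochs, `T = 25`. The encoder
draws fresh noise every epoch (stochastic regularization); evaluation uses
a fixed encoder seed, so histories are bit-identical across reruns.
The hot loop runs in float32 (weights restored to float64 on exit); the
gradient-check paths run in float64.

## 5. Quantization and crossbar layout (`quantize.py`)

Per layer, a symmetric max-abs scale `s = max(|w|, |w_a|)/8` maps weights
to integer codes `clip(round(w/s), −8, 7)` — signed 4-bit two's complement
under the base `{−2³, 2², 2¹, 2⁰}` (so −5 ↔ `1011`, −8 ↔ `1000`,
−1 ↔ `1111`, 7 ↔ `0111`). Bit 1 is stored as a low-resistance cell, bit 0
as high resistance.

Each conv kernel unrolls along the input-channel direction into a slender
bar of `C_in·kernel_w` rows × 4 bit columns (sign leftmost); the row order
matches the im2col window order, so one window drive equals one column
read. Integrative and adaptive groups of the same output channel are
adjacent (I₁,A₁,I₂,A₂,…) and share row addressing. FC matrices map one row
per input. Bit matrices split into tiles of ≤128 rows × ≤128 columns, with
column cuts on 4-bit group boundaries. The mapping is lossless: tests
reassemble the exact integer codes from the tiles.

## 6. Compute-in-memory engine (`crossbar.py`)

Device defaults: `G_LRS = 1e−4 S`, `G_HRS = 1e−7 S` (on/off 1000, must
exceed 100), `V_read = 0.2 V`; `G_HRS = 0` models an infinite on/off
ratio. Rows are driven in batches of at most **six**; per batch each bit
line sums `V·G` over active rows (Kirchhoff). The four currents of a group
merge with weights {−8, 4, 2, 1}; the sign line is connected only when its
current exceeds the all-HRS background `6·I_HRS` (i.e. at least one
selected weight is negative). Digital correction subtracts the expected
HRS background (`7·n·I_HRS` gated, `−n·I_HRS` connected for `n` active
rows) and divides by `I_LRS − I_HRS`. With ideal devices this recovers
exact integer dot products (verified exhaustively: 16 weight codes × 64
input patterns), and full-network crossbar inference equals the digital
quantized network prediction-for-prediction.

Implementation note: since magnitude lines are never gated, their
per-batch currents sum to one full-row matrix product with pre-merged
column weights {4,2,1}; only sign lines are evaluated per six-row batch.
This is an exact algebraic rearrangement, not an approximation.

Non-idealities:
- conductance variation: multiplicative `Uniform(1 − r/2, 1 + r/2)` per
  cell, split into a device-to-device part (drawn once at programming) and
  a cycle-to-cycle part (redrawn every read) via `c2c_share`;
- stuck-at faults: each cell is pinned to LRS with `p_SAL` or HRS with
  `p_SAH` regardless of the programmed bit, i.i.d. by default or clustered
  by whole rows/columns.

All randomness flows from explicit seeds; `sweep_nonideality` re-programs
each grid point with ≥20 independent device seeds and reports mean ± sd.

## 7. Complexity model (`complexity.py`)

Cycle counts for a frame-based CNN vs the spiking network of identical
structure, with 1-D kernels (`KH = 1`, `MH = 1`):

    T_CNN  = Σ_conv MH·MW·(KH·KW + KH + KW − 1)·C_in·C_out·Ops·bit  +  Σ_fc N_in·N_out·Ops·bit
    T_SCNN = Σ_conv MH·MW·(KH + KW − 1)·C_in·C_out·Ops·bit·t        +  Σ_fc N_in·N_out·Ops·bit·t

Defaults: multiply = 10 cycles / 32-bit data for the CNN, add = 1 cycle /
1-bit data over `t = 25` steps for the spiking network; pooling is free.
On the default topology: T_CNN = 286,543,360, T_SCNN = 14,220,300,
reduction **95.04 %** (the package's headline "over 92 %" figure).

## 8. Synthetic data (`data.py`)

Four fixed Gaussian-bump P-QRS-T templates on a 251-sample window
(R peak at index 125): normal, wide-QRS (ventricular-like), absent-P with
retrograde bump (supraventricular-like), and small-R/dominant-T
(fusion-like). Per beat: ±3-sample timing jitter, ±10 % amplitude and
width jitter, a 0.03-amplitude baseline sine, white noise (σ = 0.05
default), then min-max normalization to [0,1]. Splits are stratified
4:1 (floor(0.8·n) per class to train). Problem sizes used in tests
(beats per class, epochs, `T`) are this package's own choices, sized to
the test-time budget.

The WFDB path reads `.hea` headers, format-212 signals (three bytes per
two 12-bit two's-complement samples) and MIT-format annotations (6-bit
type code + 10-bit interval, with SKIP/AUX/NUM/SUB/CHN handling), and maps
annotation symbols to the four classes through an editable table
(`DEFAULT_CLASS_MAP`, AAMI-style grouping — a package assumption, not a
property of any recording). Tests verify the reader byte-for-byte against
fixture records synthesized in the tests themselves.

## 9. Limitations / out of scope

- Results on the real MIT-BIH Arrhythmia Database (and any published
  accuracy for it) are **not** reproduced here: the database must be
  downloaded separately, and outcomes depend on the class map and record
  selection. `scripts/mitbih_eval.py` is a documented opt-in runner.
- The crossbar model is behavioral: currents are ideal linear sums; no
  wire resistance, sneak paths, ADC quantization, or transient dynamics.
  Area/power/energy are not modeled.
- Only format-212, first-channel WFDB reading is implemented.
- Training is CPU NumPy; large-scale experiments are out of scope.
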