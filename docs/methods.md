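# Methods

## Problem setting

A responsive neurostimulator for focal epilepsy records a few EEG channels
over the seizure-onset zone and must flag an emerging seizure within seconds,
on an implant-class energy budget. The package models that setting as a 1 Hz
binary classification task: five electrodes at 256 Hz are re-referenced
against the central electrode to four channels, and every non-overlapping 1 s
window (N_w = 256 samples per channel) is classified ictal or interictal.
Three detector families are implemented and compared on equal footing, both
for detection quality and for estimated energy per classification.

## Signal conditioning

The conditioning chain runs in a fixed order; a pipeline runner enforces it.

1. **Invalid-segment exclusion.** Samples flagged invalid are expanded to
   whole 1 s grid periods; windowing skips any window that overlaps them.
2. **Bandpass.** 10th-order Chebyshev type-II IIR, 40 dB stopband
   attenuation, stopband edges 0.1 and 48 Hz, realized as five second-order
   sections and applied causally (single pass). Zero-phase filtering is
   deliberately not used: the target is an online embedded detector, which
   cannot filter backwards in time. The stopband subsumes 50/60 Hz mains
   noise, so no separate notch is applied.
3. **Amplitude rejection.** Every 1 s grid period containing a sample with
   |x| > 1 mV (strict inequality) on any electrode is marked invalid. The
   threshold is applied per electrode on the pre-reference signal; the 1 mV
   level passes normal EEG (~100 μV) and interictal spikes (~140 μV) while
   removing sharp transient artifacts. The operation is idempotent.
4. **Re-referencing.** Each peripheral electrode minus the central one,
   giving C = 4 analysis channels and rejecting common-mode activity.

## Feature bank (random-forest input)

Sixteen features per channel per window, 64 in total, in a fixed order.
Moment features use the population 1/N_w convention throughout; skewness and
kurtosis normalize by the population standard deviation and return 0 on a
constant window. The zero-mean residuals and their squares are computed once
per window and shared, matching the operation accounting below.

Amplitude entropy is not pinned down by a standard definition, so the
package uses the Shannon entropy (bits) of a 16-bin histogram of the window's
samples over [min, max], with 0·log 0 := 0; the bin count is configurable.
A 16-bin histogram keeps the cost bounded and the value finite on all inputs.

The power spectrum is |DFT(hann·x)|² one-sided (L = 129 bins, Δf = 1 Hz).
No ×2 interior-bin correction is applied: spectral entropy, the
epileptogenicity index and band-power *comparisons* are scale-free, and the
absolute band-power scale is a convention which the tests fix explicitly.
Band edges are inclusive bin ranges (theta 4–8, alpha 8–13, beta 13–30,
gamma 30–45 Hz), so adjacent bands share their boundary bin; this mirrors
the summation limits i = f₁/Δf … f₂/Δf of the defining equations and is kept
as printed. A zero denominator in the epileptogenicity index (all-zero
theta+alpha power, reachable only on degenerate input) yields 0 with a
warning.

## Detectors

**Random forest.** scikit-learn, 100 trees, entropy criterion, maximum depth
10, bootstrap sampling, inverse-class-frequency weights, and 4 candidate
features per split — the explicitly stated count, which equals √16 for the
per-channel feature set even though 64 channel-specific features are fed in;
both layouts are expressible through the config.

**CNN.** Three valid-padding convolutional blocks (15×(C×25), 15×(1×11),
10×(1×5), each with batch normalization and ReLU, max-pool 4 after the first
two, dropout 0.2) and an 8/4/1 dense head; 5,614 trainable parameters for
C = 4. Inputs are divided by the training-set standard deviation and squashed
through tanh(0.2·x); at inference the piecewise-linear approximation
lintanh(x) = clip(x/1.2, −1, 1) replaces tanh (max deviation from tanh
0.1664). Training: class-weighted binary cross-entropy, Adam 10⁻³, batch
512, fixed epoch budget; a warm start from a base model (fine-tuning) is
supported and reproduces the base predictions at epoch 0.

**LSTM-RNN.** The per-channel first difference of the window (padded back to
256 steps by repeating the first difference, so the declared input length
holds) feeds a 20-cell LSTM, a time-distributed linear dense layer of 20
units, global average pooling over time, and a sigmoid unit; 2,441
parameters. Training uses batch 256 and early stopping (patience 10) on the
validation loss of one seizure record reserved from the training set; output
probabilities are median-filtered with width 3, with the edge windows
shrinking to the edge sample. The raw derivative is additionally divided by
its training-set standard deviation before entering the LSTM: μV-scale
inputs would saturate the tanh/σ gates and stall learning. This rescaling is
a stabilization choice of this implementation; it does not appear in the
energy ledger, which costs the declared derivative→LSTM→dense pipeline.

Since no deep-learning framework is part of the dependency set, both
networks run on the package's own NumPy engine (`seizenergy.nn`):
vectorized im2col convolutions, batch normalization, BPTT through the LSTM
recurrence, Adam, dropout, and early stopping with best-weight restoration.
Analytic gradients are verified against central finite differences in the
test suite, and all randomness flows from explicit seeded generators, so
training is bit-reproducible.

**Windowing protocol.** Training/validation windows use per-class strides —
16 samples for interictal, 1 for ictal (oversampling the rare class) — and
test windows are non-overlapping (stride 256 = 1 Hz). A window is labelled
ictal iff its start time lies inside an annotated seizure; partial-overlap
windows follow their start time.

## Energy model

Each classification is decomposed into per-component operation ledgers
(loads, stores, and counts per arithmetic-operation class), and energy is
E_tot = (N_load + N_store)·E_m + Σ_x N_x·E_x with 45 nm per-operation
energies (memory access 5 pJ, float add 0.9 pJ, float multiply 3.7 pJ,
compare 0.9 pJ, divide 26.3 pJ, generic one-cycle op 3.7 pJ). One MAC counts
as a single arithmetic operation at E_add + E_mult = 4.6 pJ; a square root
is costed as a division (equal cycle counts on a Cortex-M4F FPU); divisions
by a constant are multiplications by the precomputed reciprocal; instruction
overhead is excluded by design and surfaces only in the hardware-calibration
slope.

The memory-access conventions are centralized in one rule table:

* every scalar operand fetched from a working array is one load, every
  result written back one store; register accumulators and loop counters are
  free;
* a MAC costs two loads (weight + input). In the LSTM, the concatenated
  input [x_t; h_{t−1}] is fetched once per cell per step and shared by that
  cell's four gates, so only the weight load recurs per MAC — the natural
  cell-major loop structure of a microcontroller LSTM;
* sigmoid/tanh evaluations are interpolated look-up tables: 2 loads plus 4
  one-cycle ops; ReLU is one compare; |x| is one compare; log2 is one
  one-cycle op plus one table load;
* batch normalization is folded into the preceding convolution weights at
  inference and dropout is inactive, so neither costs anything;
* the power spectrum is costed as a radix-2 real FFT — (N_w/2)·log2(N_w)
  butterflies at 4 multiplies, 6 adds, 6 loads and 4 stores each — plus the
  Hann multiplies and L squared magnitudes; the DFT algorithm is otherwise
  unspecified and this is the standard embedded choice.

The random-forest classifier stage is costed at its worst case: all 100
trees traversed to depth 10 (feature load, threshold load, compare per
node) plus vote aggregation. Feature intermediates (zero-mean residuals,
squares, spectrum) are counted once per channel and shared. Closed-form
layer counts are cross-checked in the tests against a brute-force
instrumented loop that counts scalar operations on small architectures.

Under these conventions the estimated totals are RF 0.484 μJ (69.7k AOs,
69.9k MAs), CNN 7.03 μJ (490k AOs, 965k MAs) and RNN 8.06 μJ (749k AOs,
971k MAs) per classification, with the convolutional layers alone at
472.8k MACs — numbers recomputed from scratch by `scripts/acceptance.py`.

**Hardware calibration.** `calibrate_hardware` fits measured = b₀ + b₁·
estimate by OLS (statsmodels), reporting slope, offset, adjusted R² and
Pearson r. The slope absorbs instruction overhead, the offset static power.
No hardware measurements ship with the package; the operation is exercised
on synthetic linear data (exact recovery) and Monte-Carlo noise (3-SE
coverage).

## Evaluation protocol

Window level: AUC-ROC and AUC-PR over 1 s windows, verified against
exhaustive pairwise-concordance and step-integration oracles. Early-seizure
variants relabel only windows in [onset, onset+10 s) as positive; in-seizure
windows after that are excluded from the early metric rather than counted
as false — the bookkeeping for them is otherwise undefined — so early
positives are a strict subset of standard positives.

Event level, at the F1-optimal threshold (computed on windows, maximized
over observed probability values, ties toward the higher threshold):
sensitivity (≥ 1 in-seizure detection), false detections per hour with
greedy earliest-first deduplication — a counted false detection at t
suppresses further false detections in (t, t+5 s] — and mean delay from
onset to first in-seizure detection. Deduplication applies to false
detections only.

Cross-validation is leave-one-seizure-out over single-seizure records; the
RNN reserves one training record per fold for early stopping. Fold metrics
are aggregated NaN-aware (a fold can lack a class).

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the chain assumes:
zero-mean 1/f^β background (β = 1, RMS 20 μV per electrode), ictal segments
as amplitude-modulated sinusoids chirping downward across the 4–8 Hz band
(seizure rhythms typically slow as they evolve) with a 1 s onset ramp,
weighted 1.0 on peripheral and 0.5 on the central electrode so that
re-referencing retains the discharge (a focal source near the periphery),
and optional Poisson-timed half-sine transients (< 0.1 s) for artifact
tests. A single seed expands into per-component substreams, so enabling
artifacts does not perturb the background draw.

It does **not** emulate patient-specific seizure morphology, electrode-
specific noise, eye-blink/EMG artifact taxonomies, or sub-clinical seizures.
Passing the benchmark therefore demonstrates that the implementations are
correct and that the detectors separate classes whose difference is
band-limited rhythmic power — not that they reach any particular clinical
performance on real recordings.

The default benchmark is five single-seizure records of 60 s (10 s seizure
centered at 25 s, ictal amplitude 60 μV on a 20 μV background). Desk-scale
training uses a per-class cap of 512 windows per fold (seeded, applied after
the stride-1 ictal oversampling, which is highly redundant), 50 CNN epochs
and an early-stopped RNN capped at 60 epochs; at these sizes the full
three-detector leave-one-seizure-out comparison runs in minutes on one CPU
while every detector reaches median fold AUC-ROC well above 0.9.

## Numerical choices and degenerate inputs

* Constant windows: variance/MAD/line length/entropies 0; skewness and
  kurtosis 0 by convention rather than NaN.
* All-zero spectra: spectral entropy and epileptogenicity index 0 (guarded).
* Filter designs are checked for pole stability at construction and raise
  with a diagnostic otherwise.
* F1 threshold ties resolve toward the higher threshold; the moving median
  passes edge samples through unchanged.
* Networks run in float32; parameter initialization is Glorot-uniform from
  the run seed, LSTM forget-gate biases start at 1.
* EDF output is 16-bit with a symmetric physical range padded 1%, so the
  quantization step is ~2·1.01·max|x|/65535 μV; recordings are truncated to
  whole 1 s data records on write.

## Known limitations

* The energy model's load/store accounting assumes a plain scalar
  microcontroller datapath; register blocking, SIMD, caches and compiler
  loop transforms are out of scope and are absorbed by the calibration
  slope in practice.
* No pre-trained base model ships (there is no public training corpus), so
  CNN fine-tuning is exercised mechanically (warm start) rather than from a
  clinically pre-trained state.
* The synthetic benchmark's class separation is deliberately strong; it is
  a correctness benchmark, not a difficulty benchmark.
* Sampling rates whose windows are not whole seconds of samples are
  rejected rather than resampled.
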