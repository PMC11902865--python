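# Methods

This note records the models, numerical choices and known limitations of
the painq pipeline. All quantities it mentions are computed by the test
suite or by `scripts/acceptance.py`; nothing here is an external claim.

## Synthetic ECG generator

Each subject is a `SubjectProfile`: base heart rate (beats/min), RR-interval
standard deviation `hrv_sdnn` (s, the SDNN of HRV analysis), a pain class
and per-source noise amplitudes (mV). Beats are sums of five Gaussian
bumps (P, Q, R, S, T) with fixed amplitudes/offsets/widths chosen to look
like a lead-II complex; morphology realism is not a goal — the tests rely
on the generator's exact ground truth (R-bump centres), not on visual
fidelity.

RR intervals are the mean interval 60/HR modulated by a respiratory-band
sinusoid (0.25 Hz), a low-frequency sinusoid (0.10 Hz) and white jitter,
with variance split 0.4 / 0.4 / 0.2 so the RR standard deviation matches
`hrv_sdnn` (a sinusoid of amplitude A sampled at spread phases has
standard deviation A/√2). RR values are clipped to the physiological
range [0.27 s, 2 s]. Pain classes map monotonically to cardiovascular
state — low: 65 bpm / SDNN 60 ms, medium: 80 / 40, high: 95 / 22 — the
direction expected from sympathetic activation under nociception; the
magnitudes are package defaults, with ±4 bpm and ±10 % inter-subject
jitter. No nociception index (ANI-style score) is simulated; class
labels are generated directly, one per 5-minute interval.

Noise: baseline wander as two sinusoids at 0.15/0.30 Hz (default
0.10 mV), powerline at 60 Hz (configurable to 50 Hz, default 0.02 mV),
white Gaussian (default 0.03 mV). Everything is driven by one
`numpy.random.Generator` seed; identical profile + seed is bit-identical.

What the generator does *not* emulate: arrhythmia, ectopic beats,
electrode motion artefacts, multi-lead morphology, drift in heart rate
within a recording beyond the two HRV sinusoids, or any dependence of
label on time. Passing tests therefore demonstrate algorithmic
correctness on idealized cardiology, not clinical performance.

## Preprocessing

The bandpass is a 4th-order Butterworth (0.5–40 Hz) applied
forward–backward (`sosfiltfilt`), i.e. zero-phase with squared magnitude
response; the test suite checks measured tone gains against the
`sosfreqz` design oracle. Normalization is per-segment by default
(z-score; min–max optional) with a config switch for per-record
operation; a constant segment is a degenerate input and raises rather
than being silently regularized. Segmentation takes consecutive
non-overlapping 10-s windows and drops the incomplete tail; each window
inherits the pain label of the 5-minute interval containing its start.

QRS detection thresholds CWT magnitudes: eight log-spaced scales with
centre frequencies 10–25 Hz (the QRS energy band) are summed into an
envelope; the threshold is `threshold_factor` (default 3.0) × the
envelope median (a robust scale statistic); local maxima above threshold
at least one refractory period (default 0.2 s) apart are kept; a
refinement pass enforces the minimum plausible RR interval (0.27 s),
keeping the stronger of two conflicting peaks. Detection quality is
scored by greedy one-to-one matching against ground truth at ±50 ms.

## Morse-wavelet scalograms

The analytic generalized Morse wavelet is defined in the frequency
domain, ψ̂(ω) = H(ω)(ω/ω₀)^β e^−(ω/ω₀)^γ, and evaluated in log-space so
the γ-power never overflows. Defaults β = 3, γ = 60 follow the printed
parameterization even though it inverts the common convention (γ ≈ 3
with time–bandwidth βγ ≈ 60); with γ = 60 the wavelet is a sharp
band-pass with a soft cubic low-frequency skirt. Both are configurable.
ω₀ defaults to (γ/β)^{1/γ}, which puts the undilated wavelet's peak
response at exactly 1 rad/sample, so scale a responds maximally to
fs/(2πa) Hz; this is the scale↔frequency map used everywhere.

Coefficients are computed in the Fourier domain,
W(a,·) = ifft(X(ω)·√a·ψ̂(aω)), the L2 (1/√a) normalization. The
640 × 640 scalogram uses 640 log-spaced scales covering 0.5–40 Hz (the
analysis passband) and reduces the 5120-sample time axis by factor-8
block averaging of magnitudes. Images are per-scalogram min–max scaled
to [0, 1]; an all-constant scalogram maps to zeros by convention.

## Quantum simulator

Little-endian state vectors (qubit j = bit j of the basis index),
exact expectations (infinite-shot limit; a seeded shot-sampling mode
exists but is off by default). Rotations use R_a(θ) = e^{−iθP_a/2};
layers apply Rx, Ry, Rz per qubit (order configurable, since the
figure-level description and the layer equation disagree) followed by
the entangler: `cz_chain` (CZ on neighbouring pairs every layer,
default) or `cnot_brick` (even pairs in layer 2, odd pairs in layer 3,
chains elsewhere — the circuit-diagram reading). Parameters initialize
uniform(−π, π) under the run seed.

Gradients use the parameter-shift rule, exact for Pauli rotations:
∂⟨A⟩/∂θ_k = ½[⟨A⟩(θ_k+π/2) − ⟨A⟩(θ_k−π/2)]. For speed, all 2P shifted
circuit variants are evaluated in one vectorized pass using a compiled
representation (combined 2×2 rotation matrix per qubit per layer;
entanglers precomputed as diagonal sign vectors for CZ or basis
permutations for CNOT chains). The compiled path is algebraically
identical to the per-gate path and the suite asserts their agreement,
plus agreement with dense kron-assembled unitaries for n ≤ 4 and with
central finite differences on the full 9-qubit, 4-layer circuit.

## Hybrid model and training

The classifier follows the transfer-learning pattern: a frozen
convolutional backbone, a trainable quantum circuit, a trainable linear
+ softmax head. The default backbone (`eq3_stack`) is four
conv(3×3, stride 2) → batch-norm → ReLU blocks with widths 8/32/128/512
and global average pooling, He-initialized under a seed; a lighter
residual variant (`resnet18_style`) is available. No pretrained weights
are used or required.

Backbone activations are non-negative and share a dominant mean
direction (measured pairwise cosine ≈ 0.9997 on scalogram features), so
raw amplitude encodings of different inputs are nearly parallel and the
circuit's Pauli-Z readout cannot discriminate. The pipeline therefore
standardizes features per dimension using training-split statistics
before encoding. The head is zero-initialized: with a frozen upstream
representation, early SGD then builds class-centroid directions in
measurement space, which is the behaviour a small learning rate
(default η = 0.001) can realize within a couple hundred epochs, whereas
a randomly initialized head would have to first un-learn an arbitrary
decision boundary.

Loss: L = CE(batch mean) + α·γ_q·Σ_l Σ_{i,j} |⟨ψᵢˡ|ψⱼˡ⟩|² + β‖W‖², with
α, γ_q kept as separate printed factors (defaults 0.01 and 1), ‖W‖²
over the head weights, and the overlap sum taken over the per-sample
states of the minibatch after each tracked layer (default: final layer
only; i = j diagonal terms, each ≡ 1, are included as printed). A
consequence of unitarity worth recording: every sample in a batch
passes through the *same* parameterized unitary, so
⟨ψᵢˡ|ψⱼˡ⟩ = ⟨enc_i|U†U|enc_j⟩ = ⟨enc_i|enc_j⟩ — the penalty is exactly
invariant under the circuit angles. It is logged and contributes to the
loss value, acts on nothing trainable while the backbone is frozen, and
its angle-gradient is identically zero (the property test
`test_penalty_invariant_under_circuit_parameters` verifies this).
Probabilities at the true label are clamped at 1e-12 with a warning.

Optimization is plain SGD, θ ← θ − η∇L: analytic gradients for the head,
parameter-shift for the circuit angles, chained through dL/dm. Batches
are drawn by seeded permutation each epoch; the tail partial batch is
dropped. A convergence diagnostic reports min_s‖∇L‖² against the convex
SGD bound 2(L(θ₀) − L*)/(ηt), using the whole-history minimum loss as
the L* estimate (a per-step running minimum would make the first-step
bound vacuously zero); it flags violations without raising, since the
hybrid objective is not convex.

Metrics: overall accuracy plus macro one-vs-rest sensitivity,
specificity and F1 (the averaging scheme is a package choice;
cross-checked against scikit-learn in the tests).

## Federated simulation

Clients are in-process; each round the server broadcasts global
parameters, clients train locally (`HybridTrainer` keeps its RNG and
momentum-free state across rounds), and the server takes the
sample-count-weighted elementwise mean. With one client, averaging is
the identity and the federated trajectory equals centralized training
step for step — asserted exactly in the suite. Subject-wise 70/15/15
splits use seeded permutation with largest-remainder rounding; no
subject ever appears in two partitions. Homomorphic encryption and
differential privacy are out of scope; a seeded Gaussian-noise hook on
published client updates exists (`update_noise_std`, default 0) as a
perturbation mechanism only and is deliberately not described as
differential privacy, which would require a calibrated mechanism and an
accounted budget.

## Problem sizes and defaults

Desk-scale defaults keep every run on one CPU: the training sanity task
uses 30 samples (3 × 10) of 512-d separable features, batch size 4,
η = 0.001, at most 200 epochs with early stop once ≥ 90 % train accuracy
is reached (typically 10–20 epochs). The batch size matters at this
learning rate: the update count, not the step size, limits convergence,
and small minibatches give proportionally more SGD steps per epoch at
essentially the same cost (the parameter-shift workload scales with
samples processed, not with the number of batches). The miniature
end-to-end run in the acceptance script uses 12 subjects × 60 s
(72 scalograms), η = 0.1 and 80 epochs — the larger learning rate was
set by a coarse pilot and suits the tiny sample count; its held-out
accuracy (~0.5–0.6 versus 1/3
chance) reflects the 9-measurement bottleneck with a random frozen
backbone and is reported as-is. Clinical-scale numbers are out of scope:
they require non-public patient data and a pretrained backbone.

## Known limitations

- The quantum penalty cannot regularize the circuit (proof above); it
  becomes active only if the upstream encoder is trained jointly, which
  the frozen-backbone design does not do.
- The simulator stores full state vectors; practical up to ~20 qubits.
- The backbone is forward-only (no conv backprop), consistent with the
  transfer-learning design; joint fine-tuning of conv weights is not
  implemented.
- QRS refinement enforces only the minimum RR bound; missed beats
  (gaps > 2 s) are not interpolated.
- Scalogram time reduction assumes the segment length is at least the
  output width (5120 ≥ 640); shorter segments need a smaller output
  size, exposed in the config.
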