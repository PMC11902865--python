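# painq

A quantum–classical hybrid pipeline for classifying pain levels (low /
medium / high) from single-channel ECG, built to be fully exercisable at
desk scale on synthetic data.

Pain perception modulates the autonomic nervous system, and that
modulation is visible in heart-rate dynamics. The pipeline turns 10-s
ECG windows (512 Hz) into time–frequency images, extracts classical
features, and classifies them with a small variational quantum circuit:

1. **Synthetic ECG** (`painq.synth`) — multi-subject PQRST signals built
   from Gaussian bump templates with class-dependent heart rate and
   heart-rate variability, realistic noise (baseline wander, powerline,
   white), exact ground-truth R-peak locations and one pain label per
   5-minute interval.
2. **Preprocessing** (`painq.preprocess`) — zero-phase Butterworth
   bandpass (0.5–40 Hz), amplitude normalization, 10-s segmentation,
   and QRS detection by thresholding continuous-wavelet-transform
   magnitudes in the 10–25 Hz band.
3. **Scalograms** (`painq.cwt`) — continuous wavelet transform with a
   generalized Morse wavelet, ψ̂(ω) = H(ω)(ω/ω₀)^β e^−(ω/ω₀)^γ with
   β = 3, γ = 60, using the L2 convention
   W(a,b) = a^{-1/2} ∫ x(t) ψ*((t−b)/a) dt. A 10-s, 512 Hz segment maps
   to a 640 × 640 magnitude image (640 log-spaced scales spanning
   0.5–40 Hz; time axis block-averaged 5120 → 640).
4. **Hybrid model** (`painq.hybrid`, `painq.qsim`) — a frozen
   convolutional feature extractor (conv → batch-norm → ReLU blocks)
   emits 512 features; amplitude encoding loads them onto 9 qubits
   (512 = 2⁹); a 4-layer circuit of Rx/Ry/Rz rotations with CZ-chain
   (or CNOT-brick) entanglers produces ⟨Z₁⟩…⟨Z₉⟩; a linear + softmax
   head yields class probabilities. Training is plain SGD with exact
   parameter-shift gradients, ∂⟨A⟩/∂θ = ½[⟨A⟩(θ+π/2) − ⟨A⟩(θ−π/2)],
   for the circuit angles and analytic gradients for the head. The loss
   is L = CE + α·L_q + β‖W‖², where L_q = γ Σ_l Σ_{i,j} |⟨ψᵢˡ|ψⱼˡ⟩|² is
   a batch-coherence penalty over per-sample circuit states.
5. **Federated simulation** (`painq.federated`) — subject-wise
   70/15/15 splits (no subject crosses partitions) and FedAvg-style
   sample-count-weighted parameter averaging over in-process clients.

The quantum simulator is written from scratch (little-endian state
vectors, exact expectations) and is verified in the test suite against
explicitly assembled dense tensor-product unitaries.

## Worked example

```python
import numpy as np
from painq import synth, preprocess, cwt, qsim, hybrid

profile = synth.SubjectProfile("demo", base_heart_rate=78.0,
                               hrv_sdnn=0.04, pain_class="medium")
record = synth.generate_record(profile, duration=60.0, seed=42)
print("samples:", len(record.samples), "| true R peaks:", len(record.r_peak_truth))

filtered = preprocess.bandpass_filter(record)
peaks = preprocess.detect_qrs(filtered)
recall, precision = preprocess.match_peaks(peaks, record.r_peak_truth, record.fs)
print(f"QRS detection: recall={recall:.3f} precision={precision:.3f}")

seg = preprocess.normalize(preprocess.segment_record(filtered)[0])
scal = cwt.cwt_transform(seg)
ridge = cwt.frequency_for_scale(
    scal.scale_axis[np.argmax(scal.magnitude.max(axis=1))], 512)
print("scalogram:", scal.magnitude.shape, f"| ridge frequency ~ {ridge:.2f} Hz")

feats = hybrid.extract_features(cwt.scalogram_to_image(scal),
                                hybrid.make_backbone("eq3_stack", seed=0))
m = qsim.run_circuit(feats, qsim.CircuitParameters.random(seed=0))
print("features:", feats.shape, "| <Z> head inputs:", np.round(m[:4], 3), "...")
```

prints

```
samples: 30720 | true R peaks: 78
QRS detection: recall=1.000 precision=1.000
scalogram: (640, 640) | ridge frequency ~ 1.29 Hz
features: (512,) | <Z> head inputs: [ 0.143  0.092 -0.088  0.025] ...
```

The 60-s record holds exactly 60 × 512 samples; every one of the 78
true beats is recovered within ±50 ms with no false detections; the
scalogram's strongest ridge sits at ~1.3 Hz, the 78 bpm heart rate; and
the 512 features pass through the 9-qubit circuit to produce the nine
Pauli-Z expectations (first four shown) that feed the classifier head.

## Command line

```
painq synth --subjects 6 --duration 60 --seed 1 --out records.h5
painq preprocess --in records.h5 --out peaks/
painq cwt --in records.h5 --out scalograms/
painq run --config config.yaml --seed 1          # full pipeline
painq fed-train --config config.yaml             # federated variant
painq eval --experiment painq_run
```

All stages read one YAML config (blocks `synth`, `preprocess`, `cwt`,
`circuit`, `model`, `train`, `federated`); every artifact (config
snapshot, logs, peak CSVs, PNG/HDF5 scalograms, per-epoch metrics,
checkpoints) lands under the experiment directory.

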