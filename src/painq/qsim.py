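"""From-scratch little-endian state-vector simulator.

Implements amplitude encoding, parameterized Pauli rotations, CZ/CNOT
entanglers, the layered variational circuit (default: 9 qubits, 4
layers), exact Pauli-Z expectation readout and parameter-shift
gradients.

Conventions
-----------
* Little-endian: qubit ``j`` is the j-th least significant bit of the
  computational-basis index.
* Rotations use the physics convention ``R_a(t) = exp(-i t P_a / 2)``:

      Rx = [[cos(t/2), -i sin(t/2)], [-i sin(t/2), cos(t/2)]]
      Ry = [[cos(t/2), -sin(t/2)], [sin(t/2), cos(t/2)]]
      Rz = diag(exp(-i t/2), exp(+i t/2))

* Measurements are exact expectations (infinite-shot limit); an optional
  seeded shot-sampling mode exists for realism.

All gate kernels accept a leading batch axis, so a whole minibatch of
states moves through the circuit in one set of vectorized operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

DEFAULT_N_QUBITS = 9
DEFAULT_LAYERS = 4
AXES = ("x", "y", "z")

_PAULI = {
    "x": np.array([[0, 1], [1, 0]], dtype=complex),
    "y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "z": np.array([[1, 0], [0, -1]], dtype=complex),
}


@dataclass
class QuantumState:
    """Normalized complex amplitude vector over 2**n basis states."""

    amplitudes: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.amplitudes.shape != (2 ** self.n,):
            raise ValueError(
                f"amplitude vector must have length 2**{self.n}")
        norm2 = float(np.sum(np.abs(self.amplitudes) ** 2))
        if abs(norm2 - 1.0) > 1e-10:
            raise ValueError(f"state not normalized: sum |a|^2 = {norm2}")


@dataclass
class CircuitParameters:
    """Rotation angles indexed (layer, qubit, axis-slot), in radians."""

    angles: np.ndarray                      # (L, n, n_axes)
    axes: tuple = AXES                      # rotation order within a layer
    entangler: str = "cz_chain"             # or "cnot_brick"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 3 or self.angles.shape[2] != len(self.axes):
            raise ValueError("angles must have shape (L, n, n_axes)")
        if self.angles.shape[0] < 1:
            raise ValueError("need at least one layer")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.entangler not in ("cz_chain", "cnot_brick"):
            raise ValueError(f"unknown entangler {self.entangler!r}")
        if any(a not in AXES for a in self.axes):
            raise ValueError("axes must be drawn from ('x', 'y', 'z')")

    @property
    def n_layers(self) -> int:
        return self.angles.shape[0]

    @property
    def n_qubits(self) -> int:
        return self.angles.shape[1]

    @classmethod
    def random(cls, n_qubits: int = DEFAULT_N_QUBITS,
               n_layers: int = DEFAULT_LAYERS, seed: int = 0,
               axes: tuple = AXES, entangler: str = "cz_chain"):
        """Uniform(-pi, pi) initialization under a run seed."""
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-np.pi, np.pi,
                             size=(n_layers, n_qubits, len(axes)))
        return cls(angles=angles, axes=axes, entangler=entangler)


# ---------------------------------------------------------------------------
# batched gate kernels (amps shape: (..., 2**n))

def rotation_matrix(axis: str, angle: float) -> np.ndarray:
    """2x2 unitary exp(-i * angle * Pauli_axis / 2)."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    c, s = np.cos(angle / 2.0), np.sin(angle / 2.0)
    if axis == "x":
        return np.array([[c, -1j * s], [-1j * s, c]])
    if axis == "y":
        return np.array([[c, -s], [s, c]], dtype=complex)
    return np.array([[np.exp(-1j * angle / 2), 0],
                     [0, np.exp(1j * angle / 2)]])


def _apply_single(amps: np.ndarray, n: int, qubit: int,
                  u: np.ndarray) -> np.ndarray:
    """Apply a 2x2 unitary to one qubit of a (batched) amplitude array."""
    lead = amps.shape[:-1]
    t = amps.reshape(lead + (2,) * n)
    axis = len(lead) + (n - 1 - qubit)  # little-endian: qubit 0 = last axis
    t = np.moveaxis(t, axis, -1)
    t = t @ u.T
    t = np.moveaxis(t, -1, axis)
    return t.reshape(lead + (2 ** n,))


def _cz_mask(n: int, q1: int, q2: int) -> np.ndarray:
    idx = np.arange(2 ** n)
    return ((idx >> q1) & 1).astype(bool) & ((idx >> q2) & 1).astype(bool)


def _apply_cz(amps: np.ndarray, n: int, q1: int, q2: int) -> np.ndarray:
    out = amps.copy()
    out[..., _cz_mask(n, q1, q2)] *= -1.0
    return out


def _apply_cnot(amps: np.ndarray, n: int, control: int,
                target: int) -> np.ndarray:
    idx = np.arange(2 ** n)
    sel = (((idx >> control) & 1) == 1) & (((idx >> target) & 1) == 0)
    src = idx[sel]
    dst = src | (1 << target)
    out = amps.copy()
    out[..., src], out[..., dst] = amps[..., dst], amps[..., src]
    return out


# ---------------------------------------------------------------------------
# public single-state operations

def amplitude_encode(features: np.ndarray, n: int = DEFAULT_N_QUBITS
                     ) -> QuantumState:
    """Map a real feature vector onto amplitudes (zero-padded, normalized)."""
    amps = _encode_batch(np.asarray(features, dtype=float)[None, :], n)[0]
    return QuantumState(amplitudes=amps, n=n)


def _encode_batch(features: np.ndarray, n: int) -> np.ndarray:
    dim = 2 ** n
    if features.shape[1] > dim:
        raise ValueError(
            f"{features.shape[1]} features exceed 2**{n} amplitudes")
    norms = np.linalg.norm(features, axis=1)
    if np.any(norms <= 1e-12):
        raise ValueError("feature vector has near-zero norm; cannot encode")
    amps = np.zeros((features.shape[0], dim), dtype=complex)
    amps[:, : features.shape[1]] = features / norms[:, None]
    return amps


def _check_qubit(n: int, *qubits) -> None:
    for q in qubits:
        if not 0 <= q < n:
            raise ValueError(f"qubit index {q} out of range for n={n}")


def apply_rotation(state: QuantumState, qubit: int, axis: str,
                   angle: float) -> QuantumState:
    _check_qubit(state.n, qubit)
    u = rotation_matrix(axis, angle)
    return QuantumState(_apply_single(state.amplitudes, state.n, qubit, u),
                        state.n)


def apply_cz(state: QuantumState, q1: int, q2: int) -> QuantumState:
    if q1 == q2:
        raise ValueError("CZ requires two distinct qubits")
    _check_qubit(state.n, q1, q2)
    return QuantumState(_apply_cz(state.amplitudes, state.n, q1, q2), state.n)


def apply_cnot(state: QuantumState, control: int, target: int) -> QuantumState:
    if control == target:
        raise ValueError("CNOT requires distinct control and target")
    _check_qubit(state.n, control, target)
    return QuantumState(_apply_cnot(state.amplitudes, state.n, control,
                                    target), state.n)


# ---------------------------------------------------------------------------
# compiled circuit path: combined per-qubit rotation matrices + precomputed
# entangler action (diagonal signs for CZ, index permutation for CNOT).
# Mathematically identical to the per-gate path; used for speed in
# run_circuit / measurement_jacobian, where thousands of shifted circuit
# variants are evaluated.

def _axis_matrices(axis: str, angles: np.ndarray) -> np.ndarray:
    """Vectorized rotation matrices, angles (...,) -> (..., 2, 2)."""
    c = np.cos(angles / 2.0)
    s = np.sin(angles / 2.0)
    out = np.empty(angles.shape + (2, 2), dtype=complex)
    if axis == "x":
        out[..., 0, 0] = c
        out[..., 0, 1] = -1j * s
        out[..., 1, 0] = -1j * s
        out[..., 1, 1] = c
    elif axis == "y":
        out[..., 0, 0] = c
        out[..., 0, 1] = -s
        out[..., 1, 0] = s
        out[..., 1, 1] = c
    else:
        out[..., 0, 0] = np.exp(-1j * angles / 2.0)
        out[..., 0, 1] = 0.0
        out[..., 1, 0] = 0.0
        out[..., 1, 1] = np.exp(1j * angles / 2.0)
    return out


def _combined_rotations(angles: np.ndarray, axes) -> np.ndarray:
    """Product over the axis slots, (..., A) angles -> (..., 2, 2)."""
    mats = _axis_matrices(axes[0], angles[..., 0])
    for k in range(1, len(axes)):
        mats = _axis_matrices(axes[k], angles[..., k]) @ mats
    return mats


@lru_cache(maxsize=64)
def _entangler_action(entangler: str, layer: int, n: int):
    """('diag', signs) or ('perm', gather-index) for a layer's entangler."""
    pairs = entangler_pairs(entangler, layer, n)
    idx = np.arange(2 ** n)
    if entangler == "cz_chain":
        signs = np.ones(2 ** n)
        for q1, q2 in pairs:
            signs[_cz_mask(n, q1, q2)] *= -1.0
        return ("diag", signs)
    f = idx.copy()
    for c, t in pairs:
        f = f ^ (((f >> c) & 1) << t)
    inv = np.empty_like(f)
    inv[f] = idx
    return ("perm", inv)


def _apply_single_multi(amps: np.ndarray, n: int, qubit: int,
                        u: np.ndarray) -> np.ndarray:
    """Apply 2x2 matrices to one qubit; u is (2,2) or (V,2,2) with a
    matching leading variant axis on amps.

    Basis index decomposes as i = hi * 2**(q+1) + bit * 2**q + lo, so a
    reshape to (..., hi, 2, lo) exposes the qubit axis without any
    transposition of the full tensor.
    """
    lead = amps.shape[:-1]
    lo = 2 ** qubit
    hi = 2 ** (n - 1 - qubit)
    if qubit == 0:  # contiguous qubit axis: right-multiply (hi, 2) rows
        t = amps.reshape(lead + (hi, 2))
        if u.ndim == 3:
            u = u.reshape((u.shape[0],) + (1,) * len(lead[1:]) + (2, 2))
        out = np.matmul(t, u.swapaxes(-1, -2))
    else:
        t = amps.reshape(lead + (hi, 2, lo))
        if u.ndim == 3:  # align the variant axis for broadcasting
            u = u.reshape((u.shape[0],) + (1,) * len(lead[1:]) + (1, 2, 2))
        out = np.matmul(u, t)  # (2,2) @ (2,lo) over broadcast leading dims
    return out.reshape(lead + (2 ** n,))


def _run_compiled(amps: np.ndarray, rotmats: np.ndarray,
                  params: CircuitParameters,
                  return_layer_states: bool = False):
    """Run all layers. ``rotmats`` is (L, n, 2, 2) or (V, L, n, 2, 2);
    in the latter case amps must carry a matching leading V axis."""
    n = params.n_qubits
    variant = rotmats.ndim == 5
    layer_states = []
    for layer in range(params.n_layers):
        for j in range(n):
            u = rotmats[:, layer, j] if variant else rotmats[layer, j]
            amps = _apply_single_multi(amps, n, j, u)
        kind, arr = _entangler_action(params.entangler, layer, n)
        amps = amps * arr if kind == "diag" else amps[..., arr]
        if return_layer_states:
            layer_states.append(amps.copy())
    return (amps, layer_states) if return_layer_states else amps


def entangler_pairs(entangler: str, layer: int, n: int) -> list:
    """(q1, q2) pairs for a layer's entangling stage (0-based layer).

    ``cz_chain``: CZ on (0,1),(1,2),...,(n-2,n-1) in every layer.
    ``cnot_brick``: CNOTs; layer 1 on even pairs (0,1),(2,3),...;
    layer 2 on odd pairs (1,2),(3,4),...; other layers chain pattern.
    """
    if n < 2:
        return []
    if entangler == "cnot_brick":
        if layer == 1:
            return [(j, j + 1) for j in range(0, n - 1, 2)]
        if layer == 2:
            return [(j, j + 1) for j in range(1, n - 1, 2)]
    return [(j, j + 1) for j in range(n - 1)]


def _apply_layer_batch(amps: np.ndarray, params: CircuitParameters,
                       layer: int) -> np.ndarray:
    n = params.n_qubits
    for j in range(n):
        for k, axis in enumerate(params.axes):
            u = rotation_matrix(axis, params.angles[layer, j, k])
            amps = _apply_single(amps, n, j, u)
    for q1, q2 in entangler_pairs(params.entangler, layer, n):
        if params.entangler == "cz_chain":
            amps = _apply_cz(amps, n, q1, q2)
        else:
            amps = _apply_cnot(amps, n, q1, q2)
    return amps


def apply_layer(state: QuantumState, params: CircuitParameters,
                layer: int) -> QuantumState:
    """One circuit layer: per-qubit rotations (axes order) then entangler."""
    if not 0 <= layer < params.n_layers:
        raise ValueError(f"layer {layer} out of range (L={params.n_layers})")
    return QuantumState(
        _apply_layer_batch(state.amplitudes[None, :], params, layer)[0],
        state.n)


def z_expectations(state: QuantumState) -> np.ndarray:
    """Exact (<Z_1>, ..., <Z_n>) from the state vector."""
    return _z_batch(state.amplitudes[None, :], state.n)[0]


def _z_batch(amps: np.ndarray, n: int) -> np.ndarray:
    probs = np.abs(amps) ** 2
    idx = np.arange(2 ** n)
    signs = 1.0 - 2.0 * ((idx[None, :] >> np.arange(n)[:, None]) & 1)
    return probs @ signs.T


def sample_z_means(state: QuantumState, shots: int, seed: int) -> np.ndarray:
    """Finite-shot estimate of the Z expectations (optional realism mode)."""
    rng = np.random.default_rng(seed)
    probs = np.abs(state.amplitudes) ** 2
    probs = probs / probs.sum()
    draws = rng.choice(2 ** state.n, size=shots, p=probs)
    bits = (draws[:, None] >> np.arange(state.n)[None, :]) & 1
    return (1.0 - 2.0 * bits).mean(axis=0)


# ---------------------------------------------------------------------------
# full circuit

def _run_batch(features: np.ndarray, params: CircuitParameters,
               return_layer_states: bool = False):
    amps = _encode_batch(features, params.n_qubits)
    rotmats = _combined_rotations(params.angles, params.axes)
    if return_layer_states:
        amps, states = _run_compiled(amps, rotmats, params, True)
        return _z_batch(amps, params.n_qubits), states
    amps = _run_compiled(amps, rotmats, params)
    return _z_batch(amps, params.n_qubits)


def run_circuit(features: np.ndarray, params: CircuitParameters,
                return_layer_states: bool = False):
    """Encode -> L layers -> Z expectations for one feature vector."""
    features = np.asarray(features, dtype=float)
    if return_layer_states:
        m, states = _run_batch(features[None, :], params, True)
        return m[0], [s[0] for s in states]
    return _run_batch(features[None, :], params)[0]


def run_circuit_batch(features: np.ndarray, params: CircuitParameters,
                      return_layer_states: bool = False):
    """Vectorized run over a (B, d) feature matrix; returns (B, n)."""
    return _run_batch(np.asarray(features, dtype=float), params,
                      return_layer_states)


def parameter_shift_gradient(features: np.ndarray,
                             params: CircuitParameters,
                             observable: int) -> np.ndarray:
    """Exact gradient of <Z_observable> w.r.t. every rotation angle.

    Parameter-shift rule: d<A>/dt = (1/2)[<A>(t + pi/2) - <A>(t - pi/2)],
    one parameter shifted at a time. Returns an array shaped like
    ``params.angles``.
    """
    _check_qubit(params.n_qubits, observable)
    jac = measurement_jacobian(np.asarray(features, float)[None, :], params)
    grad_flat = jac[0, :, observable]
    return grad_flat.reshape(params.angles.shape)


def measurement_jacobian(features: np.ndarray,
                         params: CircuitParameters) -> np.ndarray:
    """Parameter-shift Jacobian d<Z_j>/d theta_k for a feature batch.

    Returns shape (B, P, n) with P = L * n_qubits * n_axes, parameters
    flattened in C order of the angles array. Each parameter costs two
    batched circuit evaluations.
    """
    features = np.asarray(features, dtype=float)
    base = params.angles
    P = base.size
    # 2P circuit variants (each parameter shifted by +/- pi/2) evaluated
    # in one vectorized pass over a variant axis
    shifts = np.concatenate([np.eye(P), -np.eye(P)]) * (np.pi / 2.0)
    angles_v = base.ravel()[None, :] + shifts           # (2P, P)
    angles_v = angles_v.reshape((2 * P,) + base.shape)
    rotmats = _combined_rotations(angles_v, params.axes)  # (2P, L, n, 2, 2)
    amps = _encode_batch(features, params.n_qubits)       # (B, 2**n)
    amps_v = np.broadcast_to(amps[None], (2 * P,) + amps.shape).copy()
    final = _run_compiled(amps_v, rotmats, params)
    m = _z_batch(final.reshape(-1, 2 ** params.n_qubits),
                 params.n_qubits).reshape(2 * P, amps.shape[0],
                                          params.n_qubits)
    jac = 0.5 * (m[:P] - m[P:])                           # (P, B, n)
    return np.moveaxis(jac, 0, 1)


# ---------------------------------------------------------------------------
# serialization (structured text, one row per angle)

def parameters_to_text(params: CircuitParameters) -> str:
    lines = [f"# entangler={params.entangler} axes={','.join(params.axes)}",
             "layer\tqubit\taxis\tangle_rad"]
    L, n, A = params.angles.shape
    for layer in range(L):
        for j in range(n):
            for k in range(A):
                lines.append(
                    f"{layer}\t{j}\t{params.axes[k]}\t"
                    f"{float(params.angles[layer, j, k])!r}")
    return "\n".join(lines) + "\n"


def parameters_from_text(text: str) -> CircuitParameters:
    lines = [ln for ln in text.strip().splitlines() if ln]
    header = lines[0]
    assert header.startswith("#")
    meta = dict(tok.split("=") for tok in header[1:].split())
    axes = tuple(meta["axes"].split(","))
    rows = [ln.split("\t") for ln in lines[2:]]
    L = max(int(r[0]) for r in rows) + 1
    n = max(int(r[1]) for r in rows) + 1
    angles = np.zeros((L, n, len(axes)))
    axis_slot = {a: k for k, a in enumerate(axes)}
    for layer, qubit, axis, val in rows:
        angles[int(layer), int(qubit), axis_slot[axis]] = float(val)
    return CircuitParameters(angles=angles, axes=axes,
                             entangler=meta["entangler"])
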