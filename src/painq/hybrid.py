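"""Hybrid quantum-classical classifier.

Architecture: a frozen convolutional feature extractor maps a 640x640
scalogram image to a 512-dimensional vector; amplitude encoding loads
the vector onto 9 qubits (512 = 2**9); the variational circuit produces
9 Pauli-Z expectations; a linear + softmax head yields 3-class pain
probabilities.

Training follows the transfer-learning pattern: the backbone stays
frozen (seeded random initialization by default; no pretrained weights
required), while the circuit angles are updated with exact
parameter-shift gradients and the linear head with analytic gradients,
both via plain SGD, theta <- theta - eta * grad.

The loss is  L_total = CE + alpha * L_quantum + beta_reg * ||W||^2,
where L_quantum = gamma_q * sum_l sum_{i,j} |<psi_i^l | psi_j^l>|^2 over
the per-sample circuit states of a minibatch after each tracked layer.
Because all samples traverse the same unitary, those overlaps equal the
overlaps of the encoded inputs: the penalty is invariant under the
circuit angles (zero gradient) and acts as a logged batch-coherence
measure rather than a trainable regularizer; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import qsim

N_CLASSES = 3
FEATURE_DIM = 512
PROB_CLAMP = 1e-12


# ---------------------------------------------------------------------------
# conv + BN + ReLU blocks

@dataclass
class ConvBlockParams:
    """One conv -> batch-norm -> ReLU block."""

    weights: np.ndarray        # (C_out, C_in, k, k)
    bias: np.ndarray           # (C_out,)
    bn_gamma: np.ndarray       # (C_out,)
    bn_beta: np.ndarray        # (C_out,)
    running_mean: np.ndarray   # (C_out,)
    running_var: np.ndarray    # (C_out,)
    eps: float = 1e-5
    stride: int = 1

    def __post_init__(self) -> None:
        if np.any(self.running_var < 0):
            raise ValueError("running variance must be >= 0")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def conv2d(x: np.ndarray, weights: np.ndarray, bias: np.ndarray,
           stride: int = 1) -> np.ndarray:
    """Valid 2-D cross-correlation, (B, C_in, H, W) -> (B, C_out, H', W')."""
    B, C_in, H, W = x.shape
    C_out, C_in2, k, _ = weights.shape
    if C_in != C_in2:
        raise ValueError(f"channel mismatch: input {C_in}, kernel {C_in2}")
    if H < k or W < k:
        raise ValueError("input spatially smaller than kernel")
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (B, C_in, H', W', k, k)
    out = np.tensordot(win, weights, axes=([1, 4, 5], [1, 2, 3]))
    return np.moveaxis(out, 3, 1) + bias[None, :, None, None]


def conv_block_forward(x: np.ndarray, p: ConvBlockParams,
                       training: bool = False) -> np.ndarray:
    """ReLU(BN(conv(x) + b)); batch stats when training, running otherwise."""
    z = conv2d(x, p.weights, p.bias, stride=p.stride)
    if training:
        mu = z.mean(axis=(0, 2, 3))
        var = z.var(axis=(0, 2, 3))
    else:
        mu, var = p.running_mean, p.running_var
    zn = (z - mu[None, :, None, None]) / np.sqrt(
        var[None, :, None, None] + p.eps)
    zn = p.bn_gamma[None, :, None, None] * zn + p.bn_beta[None, :, None, None]
    return np.maximum(zn, 0.0)


def _he_block(c_in: int, c_out: int, k: int, stride: int,
              rng: np.random.Generator) -> ConvBlockParams:
    w = rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(
        2.0 / (c_in * k * k))
    return ConvBlockParams(weights=w, bias=np.zeros(c_out),
                           bn_gamma=np.ones(c_out), bn_beta=np.zeros(c_out),
                           running_mean=np.zeros(c_out),
                           running_var=np.ones(c_out), stride=stride)


class Eq3Backbone:
    """Four stride-2 conv blocks then global average pooling to 512."""

    widths = (8, 32, 128, 512)

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.blocks = []
        c_in = 1
        for c_out in self.widths:
            self.blocks.append(_he_block(c_in, c_out, 3, 2, rng))
            c_in = c_out

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = image[None, None, :, :]
        for blk in self.blocks:
            x = conv_block_forward(x, blk, training=False)
        return x.mean(axis=(2, 3))[0]


class ResNet18StyleBackbone:
    """Lighter residual variant: 7x7/4 stem then four residual stages."""

    widths = (64, 128, 256, 512)

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.stem = _he_block(1, self.widths[0], 7, 4, rng)
        self.stages = []
        c_in = self.widths[0]
        for c_out in self.widths:
            main = _he_block(c_in, c_out, 3, 2, rng)
            proj = _he_block(c_in, c_out, 1, 2, rng)
            self.stages.append((main, proj))
            c_in = c_out

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = conv_block_forward(image[None, None, 3:, 3:], self.stem)
        for main, proj in self.stages:
            y = conv_block_forward(x, main)
            s = conv_block_forward(x, proj)
            h = min(y.shape[2], s.shape[2])
            w = min(y.shape[3], s.shape[3])
            x = y[:, :, :h, :w] + s[:, :, :h, :w]
        return x.mean(axis=(2, 3))[0]


def make_backbone(kind: str = "eq3_stack", seed: int = 0):
    if kind == "eq3_stack":
        return Eq3Backbone(seed)
    if kind == "resnet18_style":
        return ResNet18StyleBackbone(seed)
    raise ValueError(f"unknown backbone {kind!r}")


def extract_features(image: np.ndarray, backbone=None) -> np.ndarray:
    """Deterministic 512-d feature vector from a grayscale image."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if backbone is None:
        backbone = Eq3Backbone(seed=0)
    feats = backbone(image)
    if feats.shape != (FEATURE_DIM,):
        raise RuntimeError(f"backbone emitted {feats.shape}, expected 512")
    return feats


# ---------------------------------------------------------------------------
# head, loss, metrics

def classify(m: np.ndarray, weights: np.ndarray,
             bias: np.ndarray) -> np.ndarray:
    """Softmax over linear logits; supports (n,) or (B, n) inputs."""
    m_arr = np.asarray(m, dtype=float)
    single = m_arr.ndim == 1
    logits = np.atleast_2d(m_arr) @ weights.T + bias[None, :]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    return p[0] if single else p


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.01     # weight of the quantum penalty
    beta_reg: float = 1e-4  # weight of the squared-norm regularizer
    gamma_q: float = 1.0    # inner scale of the quantum penalty

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta_reg, self.gamma_q) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossComponents:
    total: float
    cross_entropy: float
    quantum_penalty: float
    weight_decay: float


def quantum_penalty(layer_states, gamma_q: float = 1.0) -> float:
    """gamma_q * sum over tracked layers of sum_{i,j} |<psi_i|psi_j>|^2.

    ``layer_states`` is a list of (B, 2**n) complex arrays (one per
    tracked layer). Diagonal i = j terms (each exactly 1) are included,
    as printed.
    """
    total = 0.0
    for states in layer_states:
        g = states @ states.conj().T
        total += float(np.sum(np.abs(g) ** 2))
    return gamma_q * total


def hybrid_loss(probs: np.ndarray, labels: np.ndarray, layer_states,
                weights_l2: float, lw: LossWeights) -> LossComponents:
    """Total training loss and its components.

    Cross-entropy is averaged over the batch; the quantum penalty and
    the ||W||^2 term are added as printed. ``weights_l2`` is the squared
    Frobenius norm of the classical trainable weights.
    """
    probs = np.atleast_2d(probs)
    labels = np.asarray(labels, dtype=int)
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true < PROB_CLAMP):
        warnings.warn("probability at true label clamped to 1e-12",
                      stacklevel=2)
        p_true = np.maximum(p_true, PROB_CLAMP)
    ce = float(-np.mean(np.log(p_true)))
    qp = lw.alpha * quantum_penalty(layer_states, lw.gamma_q)
    wd = lw.beta_reg * float(weights_l2)
    return LossComponents(total=ce + qp + wd, cross_entropy=ce,
                          quantum_penalty=qp, weight_decay=wd)


def sgd_step(params: dict, gradients: dict, lr: float) -> dict:
    """theta <- theta - eta * grad, elementwise over named arrays."""
    out = {}
    for name, value in params.items():
        g = gradients[name]
        if np.asarray(g).shape != np.asarray(value).shape:
            raise ValueError(f"gradient shape mismatch for {name!r}")
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for {name!r}")
        out[name] = value - lr * np.asarray(g)
    return out


def convergence_diagnostic(loss_history, grad_norm_history,
                           lr: float) -> dict:
    """Check min_s ||grad||^2 against the SGD bound 2(L0 - L*)/(eta t).

    Diagnostic only: violations are flagged, not raised, since the bound
    is a convex-case guarantee.
    """
    loss = np.asarray(loss_history, dtype=float)
    gnorm = np.asarray(grad_norm_history, dtype=float)
    if len(loss) < 2 or len(loss) != len(gnorm):
        raise ValueError("need >= 2 recorded steps with matching lengths")
    l_star = loss.min()  # best loss seen over the whole run estimates L*
    t = np.arange(1, len(loss) + 1)
    bound = 2.0 * (loss[0] - l_star) / (lr * t)
    observed = np.minimum.accumulate(gnorm ** 2)
    return {"bound": bound, "observed_min_grad_sq": observed,
            "violations": observed > bound + 1e-12}


def evaluate(y_pred, y_true, n_classes: int = N_CLASSES) -> dict:
    """Accuracy plus macro one-vs-rest sensitivity, specificity and F1."""
    y_pred = np.asarray(y_pred, dtype=int)
    y_true = np.asarray(y_true, dtype=int)
    if len(y_true) == 0 or len(y_pred) != len(y_true):
        raise ValueError("need equal-length, non-empty label vectors")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    total = cm.sum()
    sens, spec, f1s = [], [], []
    for c in range(n_classes):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        se = tp / (tp + fn) if tp + fn else 0.0
        pr = tp / (tp + fp) if tp + fp else 0.0
        sens.append(se)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
        f1s.append(2 * pr * se / (pr + se) if pr + se else 0.0)
    return {"accuracy": float(np.trace(cm) / total),
            "sensitivity": float(np.mean(sens)),
            "specificity": float(np.mean(spec)),
            "f1": float(np.mean(f1s)),
            "confusion_matrix": cm}


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    epochs: int = 200
    batch_size: int = 4
    seed: int = 0
    backbone: str = "eq3_stack"
    entangler: str = "cz_chain"
    rot_axes: tuple = qsim.AXES  # ("x", "x", "z") = circuit-prose variant
    n_layers: int = qsim.DEFAULT_LAYERS
    n_qubits: int = qsim.DEFAULT_N_QUBITS
    penalty_layers: tuple = (-1,)  # layers tracked by the quantum penalty

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 2:
            raise ValueError(
                "batch_size must be >= 2 (pairwise quantum penalty)")


class HybridTrainer:
    """SGD trainer for circuit angles + linear head on fixed features.

    Keeps its RNG and parameters across calls to :meth:`run_epochs`, so a
    federated client that trains E epochs per round for R rounds follows
    the same trajectory as a centralized run of R*E epochs — which makes
    the 1-client federated setup exactly equivalent to centralized
    training.
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 config: TrainConfig, lw: LossWeights = LossWeights()):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels, dtype=int)
        self.config = config
        self.lw = lw
        self.rng = np.random.default_rng(config.seed)
        self.circuit = qsim.CircuitParameters.random(
            n_qubits=config.n_qubits, n_layers=config.n_layers,
            seed=config.seed, axes=tuple(config.rot_axes),
            entangler=config.entangler)
        # zero-init head: the first SGD steps then build class-centroid
        # directions in measurement space, the right starting point when
        # the backbone+circuit features are frozen or slowly moving
        self.head_w = np.zeros((N_CLASSES, config.n_qubits))
        self.head_b = np.zeros(N_CLASSES)
        self.history: list = []

    # -- parameter dict view (for federated averaging / checkpoints)
    def get_params(self) -> dict:
        return {"circuit_angles": self.circuit.angles.copy(),
                "head_w": self.head_w.copy(), "head_b": self.head_b.copy()}

    def set_params(self, params: dict) -> None:
        self.circuit = qsim.CircuitParameters(
            angles=np.asarray(params["circuit_angles"], dtype=float),
            axes=self.circuit.axes, entangler=self.circuit.entangler)
        self.head_w = np.asarray(params["head_w"], dtype=float).copy()
        self.head_b = np.asarray(params["head_b"], dtype=float).copy()

    def _forward(self, feats: np.ndarray):
        track = [i % self.config.n_layers
                 for i in self.config.penalty_layers]
        m, states = qsim.run_circuit_batch(feats, self.circuit,
                                           return_layer_states=True)
        probs = classify(m, self.head_w, self.head_b)
        return m, [states[i] for i in track], np.atleast_2d(probs)

    def _step(self, feats: np.ndarray, labels: np.ndarray) -> tuple:
        B = len(labels)
        m, tracked, probs = self._forward(feats)
        loss = hybrid_loss(probs, labels, tracked,
                           float(np.sum(self.head_w ** 2)), self.lw)
        onehot = np.eye(N_CLASSES)[labels]
        dlogits = (probs - onehot) / B
        grad_w = dlogits.T @ m + 2.0 * self.lw.beta_reg * self.head_w
        grad_b = dlogits.sum(axis=0)
        dm = dlogits @ self.head_w                     # (B, n)
        jac = qsim.measurement_jacobian(feats, self.circuit)  # (B, P, n)
        grad_angles = np.einsum("bpj,bj->p", jac, dm).reshape(
            self.circuit.angles.shape)
        # quantum penalty: zero gradient to angles (unitary invariance)
        params = self.get_params()
        grads = {"circuit_angles": grad_angles, "head_w": grad_w,
                 "head_b": grad_b}
        self.set_params(sgd_step(params, grads, self.config.learning_rate))
        gnorm = float(np.sqrt(sum(np.sum(np.asarray(g) ** 2)
                                  for g in grads.values())))
        return loss, gnorm

    def run_epochs(self, n_epochs: int) -> list:
        """Train for n_epochs; appends one summary row per epoch."""
        n = len(self.labels)
        bs = min(self.config.batch_size, n)
        rows = []
        for _ in range(n_epochs):
            order = self.rng.permutation(n)
            losses, gnorms = [], []
            for start in range(0, n - bs + 1, bs):
                idx = order[start:start + bs]
                loss, gnorm = self._step(self.features[idx],
                                         self.labels[idx])
                losses.append(loss.total)
                gnorms.append(gnorm)
            acc = self.train_accuracy()
            row = {"epoch": len(self.history) + 1,
                   "loss": float(np.mean(losses)),
                   "grad_norm": float(np.mean(gnorms)),
                   "train_accuracy": acc}
            self.history.append(row)
            rows.append(row)
        return rows

    def predict(self, feats: np.ndarray) -> np.ndarray:
        m = qsim.run_circuit_batch(np.asarray(feats, dtype=float),
                                   self.circuit)
        probs = np.atleast_2d(classify(m, self.head_w, self.head_b))
        return probs.argmax(axis=1)

    def train_accuracy(self) -> float:
        return float(np.mean(self.predict(self.features) == self.labels))


def train_hybrid(features: np.ndarray, labels: np.ndarray,
                 config: TrainConfig,
                 lw: LossWeights = LossWeights()) -> HybridTrainer:
    """Centralized training run; returns the trainer with its history."""
    trainer = HybridTrainer(features, labels, config, lw)
    trainer.run_epochs(config.epochs)
    return trainer


def fit_standardizer(features: np.ndarray) -> tuple:
    """Per-dimension mean/std of a (training) feature matrix.

    Backbone activations are non-negative and share a dominant mean
    direction, which makes raw amplitude encodings of different inputs
    nearly parallel; centering/scaling before encoding restores angular
    spread so the circuit measurements can discriminate.
    """
    features = np.asarray(features, dtype=float)
    return features.mean(axis=0), features.std(axis=0) + 1e-8


def standardize(features: np.ndarray, stats: tuple) -> np.ndarray:
    mu, sd = stats
    return (np.asarray(features, dtype=float) - mu) / sd


def make_separable_dataset(n_per_class: int = 20, dim: int = FEATURE_DIM,
                           noise: float = 0.05, seed: int = 0,
                           n_classes: int = N_CLASSES) -> tuple:
    """Linearly separable 3-class feature set for training sanity checks.

    Class means occupy disjoint coordinate blocks (orthogonal
    directions), so after amplitude encoding the classes map to
    near-orthogonal quantum states.
    """
    rng = np.random.default_rng(seed)
    block = dim // n_classes
    X, y = [], []
    for c in range(n_classes):
        mean = np.zeros(dim)
        mean[c * block:(c + 1) * block] = rng.choice(
            [-1.0, 1.0], size=block) / np.sqrt(block)
        pts = mean[None, :] + noise * rng.standard_normal(
            (n_per_class, dim)) / np.sqrt(dim)
        X.append(pts)
        y.extend([c] * n_per_class)
    return np.vstack(X), np.asarray(y, dtype=int)
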