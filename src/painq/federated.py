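"""Simulated cross-client federated training.

Clients live in one process: each round the server broadcasts the
global parameters, every client trains locally for a fixed number of
epochs on its own (subject-exclusive) data, and the server replaces the
global model with the sample-count-weighted elementwise mean of the
client parameters (FedAvg-style aggregation). Subject-wise splitting
guarantees no individual contributes to more than one of
train/validation/test.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .hybrid import HybridTrainer, LossWeights, TrainConfig, evaluate

PARTITIONS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class SplitAssignment:
    """subject_id -> partition mapping with the fractions that built it."""

    mapping: dict
    fractions: tuple

    def subjects(self, partition: str) -> list:
        return [s for s, p in self.mapping.items() if p == partition]

    def validate(self) -> None:
        for s, p in self.mapping.items():
            if p not in PARTITIONS:
                raise ValueError(f"subject {s} in unknown partition {p!r}")


@dataclass
class ClientUpdate:
    client_id: str
    parameters: dict  # name -> array
    n_samples: int
    round: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")


def subject_wise_split(subjects, fractions=DEFAULT_FRACTIONS,
                       seed: int = 0) -> SplitAssignment:
    """Random permutation, contiguous assignment, largest-remainder sizes."""
    subjects = list(subjects)
    if len(subjects) < len(PARTITIONS):
        raise ValueError("fewer subjects than partitions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n = len(subjects)
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    by_frac = np.argsort([-(r - np.floor(r)) for r in raw], kind="stable")
    for i in range(rem):
        counts[by_frac[i]] += 1
    mapping = {}
    pos = 0
    for part, cnt in zip(PARTITIONS, counts):
        for k in order[pos:pos + cnt]:
            mapping[subjects[k]] = part
        pos += cnt
    return SplitAssignment(mapping=mapping, fractions=tuple(fractions))


def federated_average(updates) -> dict:
    """Sample-count-weighted elementwise mean of client parameters."""
    if not updates:
        raise ValueError("need at least one client update")
    names = set(updates[0].parameters)
    for u in updates:
        if set(u.parameters) != names:
            raise ValueError("parameter names differ across clients")
    total = sum(u.n_samples for u in updates)
    out = {}
    for name in names:
        shape = np.asarray(updates[0].parameters[name]).shape
        acc = np.zeros(shape, dtype=float)
        for u in updates:
            arr = np.asarray(u.parameters[name], dtype=float)
            if arr.shape != shape:
                raise ValueError(f"shape mismatch for parameter {name!r}")
            acc += (u.n_samples / total) * arr
        out[name] = acc
    return out


@dataclass
class FederatedResult:
    global_params: dict
    history: list = field(default_factory=list)  # one dict per round
    trainers: list = field(default_factory=list)


def run_federated(clients, rounds: int, local_epochs: int,
                  config: TrainConfig, lw: LossWeights = LossWeights(),
                  validation: tuple | None = None,
                  update_noise_std: float = 0.0,
                  noise_seed: int = 0) -> FederatedResult:
    """FedAvg loop over in-process clients.

    ``clients`` is a list of (features, labels) tuples, one per client;
    all recordings of a subject must sit inside a single client (the
    caller builds clients from a subject-wise split). ``validation``,
    if given, is a (features, labels) pair held at the server for
    global metrics each round.

    The round counter is the model version: round r trains on the
    version-(r-1) global parameters and publishes version r.

    ``update_noise_std`` optionally adds seeded Gaussian noise to each
    client's published parameters (a perturbation hook only; no formal
    privacy guarantee is implied or claimed).
    """
    if not clients:
        raise ValueError("need at least one client")
    noise_rng = np.random.default_rng(noise_seed)
    trainers = [HybridTrainer(f, y, config, lw) for f, y in clients]
    global_params = trainers[0].get_params()
    result = FederatedResult(global_params=global_params, trainers=trainers)
    for rnd in range(1, rounds + 1):
        updates = []
        round_losses = []
        for i, tr in enumerate(trainers):
            tr.set_params(global_params)
            try:
                rows = tr.run_epochs(local_epochs)
            except Exception as exc:
                raise RuntimeError(
                    f"round {rnd}: client {i} training failed: {exc}"
                ) from exc
            round_losses.extend(r["loss"] for r in rows)
            published = tr.get_params()
            if update_noise_std > 0:
                published = {k: v + update_noise_std
                             * noise_rng.standard_normal(v.shape)
                             for k, v in published.items()}
            updates.append(ClientUpdate(
                client_id=f"client{i}", parameters=published,
                n_samples=len(tr.labels), round=rnd))
        global_params = federated_average(updates)
        row = {"round": rnd,
               "mean_client_loss": float(np.mean(round_losses))}
        if validation is not None:
            probe = trainers[0]
            saved = probe.get_params()
            probe.set_params(global_params)
            vx, vy = validation
            metrics = evaluate(probe.predict(vx), vy)
            row["val_accuracy"] = metrics["accuracy"]
            probe.set_params(saved)
        result.history.append(row)
    result.global_params = global_params
    return result


def history_to_csv(history, path) -> None:
    if not history:
        return
    keys = list(history[0].keys())
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=keys)
        w.writeheader()
        for row in history:
            w.writerow(row)
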